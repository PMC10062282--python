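"""Watch a data stream for a parameter change in real time.

Fits the curve on historical data, simulates the monitoring threshold from
the limit law, then feeds online observations to the one-pass detector.
Halfway through the stream the growth-rate parameter doubles; the printed
stopping time shows how quickly the statistic reacts.
"""

import numpy as np

import expectmon as em

rng = np.random.default_rng(1)
model = em.gompertz2_model()
beta0, beta1 = np.array([10.0, 5.0]), np.array([10.0, 10.0])
m, horizon, gamma, alpha = 200, 100, 0.1, 0.05

x_hist = rng.uniform(0.0, 1.0, m)
y_hist = model.predict(x_hist.reshape(-1, 1), beta0) + rng.standard_normal(m)
fit = em.fit_expectile(model, x_hist, y_hist, tau=0.5)

# closed-end threshold for T = horizon / m
L = em.L_of_T(horizon / m, closed_end=True)
threshold = em.critical_value(model.p, gamma, L, alpha, n_paths=50_000, seed=3)
print(f"monitoring threshold c_{{{alpha}}}({gamma}) = {threshold:.4f}  (closed-end, L={L:.3f})")

# online stream: no change for the first 50 observations, then beta_2 doubles
change_at = 50
def stream():
    for k in range(horizon):
        xk = rng.uniform(0.0, 1.0)
        beta = beta0 if k < change_at else beta1
        yield [xk], float(model.predict(np.array([[xk]]), beta)[0] + rng.standard_normal())

result = em.run_monitor(fit, stream(), gamma=gamma, threshold=threshold, horizon=horizon)

if result.detected:
    print(f"change detected at online index k = {result.k_hat} "
          f"(absolute observation {result.absolute_index}; true change after {change_at})")
else:
    print("no change detected over the horizon")
print(f"max statistic so far: {result.max_stat:.4f}")
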