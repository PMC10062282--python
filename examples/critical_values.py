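"""Critical values of the weighted Wiener-supremum limit law.

The no-change distribution of the monitoring statistic depends only on the
parameter dimension p, the boundary exponent gamma and the monitoring
range L (1 for open-end, T/(1+T) for a closed-end horizon ratio T) — not
on the regression function or the unknown parameters.  This prints a small
table of simulated 95% points and checks the p=1, gamma=0 entry against
the analytic reflection-series value.
"""

from scipy import optimize

import expectmon as em

print(f"{'p':>2} {'gamma':>6} {'mode':>10} {'L':>7} {'c_0.05':>8}")
for p in (1, 2, 3):
    for gamma in (0.0, 0.1, 0.25):
        for mode, T in (("open", None), ("closed T=0.5", 0.5)):
            L = em.L_of_T(T, closed_end=T is not None)
            c = em.critical_value(p, gamma, L, 0.05, n_paths=50_000, n_grid=5_000, seed=11)
            print(f"{p:>2} {gamma:>6.2f} {mode:>12} {L:>7.4f} {c:>8.4f}")

b95 = optimize.brentq(lambda b: em.sup_abs_wiener_cdf(b) - 0.95, 1.0, 4.0)
print(f"\nanalytic p=1, gamma=0, open-end 95% point: {b95:.4f} (simulated value above should agree)")
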