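"""A small Monte-Carlo study of the test's size and power.

Runs one level cell (no change; the rejection rate should sit near the
5% nominal level) and one power cell (the growth-rate parameter doubles
immediately after the historical block) of the Gompertz design at reduced
replication counts, and prints the summaries the larger study tabulates.
"""

import time

import expectmon as em
from expectmon.simulation import ErrorDist, SimDesign

common = dict(
    model=em.gompertz2_model(),
    beta0=(10.0, 5.0),
    m=200,
    dist=ErrorDist("gaussian", 0.0, 1.0),
    tau=0.5,
    n_reps=200,
    seed=5,
    cv_paths=50_000,
    cv_grid=5_000,
)

t0 = time.time()
level = em.run_level_experiment(
    SimDesign(horizon_rule="half_m", k0_rule="none", **common)
)
print(f"level  (no change, T_m = m/2)   : {100 * level.rejection_rate:5.2f}%  "
      f"threshold {level.threshold:.4f}")
print(f"  estimates: beta1 {level.est_mean[0]:.2f} ({level.est_sd[0]:.3f}), "
      f"beta2 {level.est_mean[1]:.2f} ({level.est_sd[1]:.3f})")

power = em.run_power_experiment(
    SimDesign(horizon_rule="half_m", k0_rule="immediate", beta1=(10.0, 10.0), **common)
)
print(f"power  (beta2 doubles at k0 = 1): {100 * power.rejection_rate:5.2f}%  "
      f"threshold {power.threshold:.4f}")
print(f"  detection location (0 = first, 1 = last online obs): "
      f"mean {power.mean_location:.2f}, median {power.median_location:.2f}")
print(f"[{time.time() - t0:.0f}s for 2 x {common['n_reps']} replications]")
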