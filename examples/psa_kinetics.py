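"""PSA kinetics: velocity and doubling time.

Samples a noisy exponential PSA trajectory with a planted doubling time of
120 days and estimates velocity (linear slope) and doubling time (log-linear
slope) from the readings.
"""

import numpy as np

from pathforge import TrajectoryParams, compute_kinetics, simulate_psa_trajectory

params = TrajectoryParams(baseline=6.0, doubling_time=120.0, noise_sd=0.05)
rng = np.random.default_rng(7)
readings = simulate_psa_trajectory(params, np.arange(8) * 60 - 420, rng)

result = compute_kinetics(readings)
print(f"readings:           {result.n_readings} over days {result.interval}")
print(f"velocity:           {result.velocity:.4f} ng/ml/day "
      f"({result.velocity_per_year:.2f} ng/ml/year)")
print(f"doubling time:      {result.doubling_time_days:.1f} days (planted: 120)")
print(f"fit residual (RMS): {result.residual_std:.3f} ng/ml")

# The doubling-time estimate ln2 / slope(ln PSA ~ t) lands close to the
# planted 120 days despite 5% multiplicative reading noise; a fast doubling
# time (short) signals aggressive biochemical progression.
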