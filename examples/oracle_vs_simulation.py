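"""Validate the Monte-Carlo engine against the exact total-score law.

On a small 10-question instrument the exact total-score distribution is
computed as a Poisson-binomial mixture over the exponential latent
density, and compared with the empirical distribution of a large
simulation by total-variation (TV) distance.  TV well below 0.01 means
the simulator and the analytic model describe the same process.
"""

import numpy as np

from exptrait import (
    InstrumentSpec,
    ItemSpec,
    LatentModel,
    SimulationConfig,
    calibrate_thresholds,
    generate_prevalence_table,
    simulate_condition,
    total_pmf,
    tv_distance,
)

toy = InstrumentSpec((ItemSpec("item A", 5), ItemSpec("item B", 5)))
prevalence = generate_prevalence_table(toy, seed=11)
latent = LatentModel(rate=1.0)
spec = calibrate_thresholds(prevalence, latent, sd=2.0)

oracle = total_pmf(toy, spec, latent)
config = SimulationConfig(latent, spec, n=100_000, seed=5)
result = simulate_condition(config, toy)
empirical = np.bincount(result.totals, minlength=11) / config.n

print("score  exact-pmf  simulated")
for k in range(11):
    print(f"{k:>5}  {oracle.probabilities[k]:.5f}    {empirical[k]:.5f}")
print(f"\nTV distance: {tv_distance(empirical, oracle.probabilities):.5f}")
print("Sampling noise alone explains a TV of this size at n = 100,000.")
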