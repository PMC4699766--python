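"""Q-Q comparison: observed counts vs simulated specific energies.

If focus counts are proportional to the specific energy absorbed in a
1.6 um^3 target, the quantiles of the count distribution should lie on a
straight line against the quantiles of the simulated energy distribution,
with slope equal to the focus yield per gray.
"""

import rifvar as rv
from rifvar.population import PopulationConfig

model = rv.default_cobalt60_model()
dose = 1.0
cfg = PopulationConfig(n_nuclei=8993, dose_Gy=dose)
counts = rv.simulate_rif_counts(cfg, model, seed=5)
z = rv.sample_specific_energy(rv.energy_distribution(model, 1.6, dose), counts.size, seed=6)

res = rv.qq_compare(counts, z)
print(f"Q-Q regression at {dose} Gy, V = 1.6 um^3:")
print(f"  slope     {res.slope:8.2f}  foci per gray")
print(f"  intercept {res.intercept:8.2f}  foci (≈ sham background)")
print(f"  r^2       {res.r_squared:8.4f}")

rate = counts.mean() / dose
print(f"\nobserved mean rate: {rate:.2f} foci/Gy — the Q-Q slope tracks the"
      "\nobserved per-gray focus rate, as expected when the energy spread in"
      "\nthe matched volume carries the whole count variability.")
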