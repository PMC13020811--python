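"""Senescence evolving spontaneously from a non-aging population.

Starts from an age-flat genotype (survival and fertility identical at
every age), evolves it for a few thousand steps under resource limitation,
and prints how the evolved intrinsic mortality and fertility now depend on
adult age. A full-length study uses ~10,000 steps (see
senesim.preset_emergent_aging); this demo runs a third of that.
"""

import numpy as np
from scipy import stats

from senesim import Simulation, intrinsic_curves, preset_emergent_aging

out = Simulation(preset_emergent_aging(steps=3500), seed=7).run()
curves = intrinsic_curves(out.final_phenotypes())

adult = np.arange(10, 25)
rho_m, p_m = stats.spearmanr(adult, curves.mortality[adult])
rho_f, p_f = stats.spearmanr(adult, curves.fertility[adult])

print("evolved intrinsic traits by adult age class:")
print("age   mortality   fertility")
for age in adult[::3]:
    print(f"{age:3d}   {curves.mortality[age]:.3f}       {curves.fertility[age]:.3f}")
print(f"\nSpearman(mortality, age) = {rho_m:+.2f} (p = {p_m:.1g})")
print(f"Spearman(fertility, age) = {rho_f:+.2f} (p = {p_f:.1g})")
print("\nMortality rising and fertility falling with age were not imposed:")
print("selection is weaker at ages few individuals reach, so late-acting")
print("deleterious variants accumulate — senescence emerges on its own.")
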