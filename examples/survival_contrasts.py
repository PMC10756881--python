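"""Survival of infected vs sterile ants with and without nestmate care.

Simulates exponential 36-h survival cohorts at the published mortality
levels (93% infected in isolation, 8% infected in the nest, ...), then
estimates Kaplan-Meier mortality per group and tests pairwise hazard
differences with colony-stratified Cox models and Holm correction.
"""

import pandas as pd

from antwound.survival import kaplan_meier, mortality_at, pairwise_hazard_contrasts
from antwound.synthgen import SurvivalParams, gen_survival

params = SurvivalParams(n_per_group=40)
table = gen_survival(params, seed=1)

for group in sorted(pd.unique(table["group"])):
    curve = kaplan_meier(table, "group", group)
    print(f"{group:20s} 36-h mortality: {mortality_at(curve):5.1f}%")

contrasts = pairwise_hazard_contrasts(table, "group", strata="colony")
sig = contrasts[contrasts["p_holm"] < 0.05]
print("\nSignificant pairwise hazard contrasts (Holm-adjusted):")
print(sig[["group_a", "group_b", "z", "p_holm"]].to_string(index=False,
      float_format=lambda v: f"{v:.3g}"))
print("\nz is the Wald statistic of the group indicator in a stratified")
print("Cox model; isolation-vs-nest contrasts for infected ants should be")
print("strongly significant, sterile contrasts should not.")
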