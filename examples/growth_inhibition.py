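"""Antimicrobial growth-inhibition assay on OD600 microplate curves.

Simulates an 8-h P. aeruginosa growth assay (6 control wells, 9 wells
with metapleural-gland secretion, blanks), fits the logistic model per
well, and compares intrinsic growth rates r between conditions.
"""

from antwound.growth import compare_growth_rates, fit_plate
from antwound.synthgen import gen_growth

plate = gen_growth(seed=1)
fits = fit_plate(plate, seed=1)
print(fits.to_string(index=False, float_format=lambda v: f"{v:.4g}"))

res = compare_growth_rates(fits, control="control", treatment="mg")
print(f"\nmedian r: control = {res['median_r_control']:.3f}/h, "
      f"treated = {res['median_r_treat']:.3f}/h")
print(f"growth inhibition: {res['inhibition_pct']:.1f}% "
      f"(Mann-Whitney U = {res['U']:.0f}, p = {res['p']:.3g})")
print("\nr is the intrinsic growth rate absent resource limitation; an")
print("inhibition above 25% with a significant U test mirrors the assay's")
print("published effect of gland secretions on P. aeruginosa.")
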