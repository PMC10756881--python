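"""Wound-care behavior over 24 h: binning, smoothing, and MG-care stats.

Simulates care-event logs in which infected ants receive elevated care on
arrival and again 10-12 h post-infection, bins events into 10-min
intervals, fits the penalized binomial spline smoother per group, and
reports when infected ants receive significantly more care, the MG-care
fraction, and the care-duration contrast.
"""

from antwound.behavior import (
    bin_events,
    care_duration_test,
    fit_care_smoother,
    mg_care_fraction,
    significant_intervals,
)
from antwound.synthgen import gen_behavior

log = gen_behavior(seed=1)

fits = {}
for group in ("infected", "sterile"):
    binned = bin_events(log[log["treatment"] == group])
    fits[group] = fit_care_smoother(binned, label=group)

intervals = significant_intervals(fits["infected"], fits["sterile"], direction="a>b")
print("Intervals with significantly elevated care for infected ants:")
for a, b in intervals:
    print(f"  {a:.1f} - {b:.1f} h")

mg, total, pct = mg_care_fraction(log)
print(f"\nMG care applied in {mg}/{total} = {pct}% of care interactions")

res = care_duration_test(log)
print(f"MG-care bouts: {res['mean_mg']:.0f} ± {res['sd_mg']:.0f} s, "
      f"plain care: {res['mean_care']:.0f} ± {res['sd_care']:.0f} s "
      f"(Welch t = {res['t']:.2f}, p = {res['p']:.3g})")
print("\nThe detected intervals should overlap the configured 10-12 h")
print("window. At the study's size (6 ants per group) the duration")
print("contrast is noisy; rerun with BehaviorParams(n_per_group=30,")
print("baseline_p=0.3) to see the 85 s vs 53 s gap emerge clearly.")
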