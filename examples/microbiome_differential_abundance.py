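"""Genus-level absolute-abundance differential abundance.

Builds a synthetic 18-ASV / 11-genus count table over 40 samples with a
Pseudomonas-led pathogen bloom in infected ants, converts counts to
absolute 16S copy numbers with per-sample qPCR totals, and runs the
10,000-permutation t-test per genus with Holm correction, plus a
community-level PERMANOVA on Bray-Curtis dissimilarities.
"""

from antwound.microbiome import (
    absolute_abundance,
    aggregate_genus,
    community_permanova,
    genus_differential_abundance,
    prevalence_filter,
)
from antwound.synthgen import gen_asv_counts

table, taxonomy, meta, totals = gen_asv_counts(seed=1)
filtered = prevalence_filter(table)            # >=1% relative abundance in >=5 samples
absolute = absolute_abundance(filtered, totals)
genus = aggregate_genus(absolute, taxonomy)

diff = genus_differential_abundance(
    genus, meta["treatment"], meta["timepoint_h"], n_perm=10_000, seed=1
)
late = diff[diff["timepoint"] == 11.0].sort_values("p_holm")
print(late[["genus", "t", "p_raw", "p_holm", "direction"]].to_string(index=False))

perm = community_permanova(absolute, meta["treatment"], seed=1)
print(f"\nPERMANOVA treatment effect: F = {perm.pseudo_F:.2f}, "
      f"R^2 = {perm.r_squared:.2f}, p = {perm.p_value:.3g}")
print("Genera with small Holm-adjusted p differ in absolute copy number")
print("between sterile and infected ants at 11 h; R^2 is the fraction of")
print("community dissimilarity explained by the treatment.")
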