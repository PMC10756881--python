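"""ASV-table filtering, absolute-abundance scaling, genus aggregation,
community-level PERMANOVA and genus-level permutation differential
abundance.

Tables are pandas DataFrames with features (ASVs or genera) as rows and
samples as columns. Absolute abundances are obtained by rescaling each
sample's relative ASV proportions by its total 16S copy number measured by
qPCR, so community comparisons operate on copy-number-scale profiles.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd
from skbio.stats.ordination import pcoa as _skbio_pcoa

from .statcore import (
    PermanovaResult,
    PermTestResult,
    bray_curtis,
    holm_bonferroni,
    permanova,
    permutation_t_test,
)

__all__ = [
    "parse_genus",
    "prevalence_filter",
    "absolute_abundance",
    "aggregate_genus",
    "genus_differential_abundance",
    "community_permanova",
    "community_pcoa",
]


def parse_genus(lineage: str) -> str:
    """Extract the genus from a lineage string.

    Accepts semicolon-separated lineages with or without rank prefixes
    (``g__Pseudomonas``); a bare name is taken as the genus itself. Empty
    or missing genus fields map to ``"unclassified"``.
    """
    if lineage is None or (isinstance(lineage, float) and np.isnan(lineage)):
        return "unclassified"
    fields = [f.strip() for f in str(lineage).split(";")]
    for f in fields:
        if f.lower().startswith("g__"):
            name = f[3:].strip()
            return name if name else "unclassified"
    # no rank prefixes: last nonempty field
    for f in reversed(fields):
        if f:
            return f
    return "unclassified"


def prevalence_filter(
    table: pd.DataFrame, min_rel: float = 0.01, min_samples: int = 5
) -> pd.DataFrame:
    """Retain ASVs with at least ``min_rel`` within-sample relative
    abundance (inclusive) in at least ``min_samples`` samples.

    The sample set is unchanged; only feature rows are dropped. With the
    defaults this is the 1%-in-5-samples rule.
    """
    if not (0.0 < min_rel < 1.0):
        raise ValueError("min_rel must lie in (0, 1)")
    counts = table.to_numpy(dtype=float)
    colsums = counts.sum(axis=0)
    if np.any(colsums == 0):
        raise ValueError("samples with zero total counts are not allowed")
    rel = counts / colsums
    keep = (rel >= min_rel).sum(axis=1) >= min_samples
    return table.loc[keep]


def absolute_abundance(table: pd.DataFrame, totals: Mapping[str, float] | pd.Series) -> pd.DataFrame:
    """Rescale per-sample proportions by the sample's total 16S copy number.

    value(a, s) = count(a, s) / colsum(s) * totals(s), so each column sums
    to the sample's measured total copies.
    """
    totals = pd.Series(totals, dtype=float)
    missing = [s for s in table.columns if s not in totals.index]
    if missing:
        raise ValueError(f"missing total copy numbers for samples: {missing}")
    counts = table.to_numpy(dtype=float)
    colsums = counts.sum(axis=0)
    if np.any(colsums == 0):
        raise ValueError("samples with zero total counts are not allowed")
    props = counts / colsums
    out = pd.DataFrame(
        props * totals.loc[table.columns].to_numpy(),
        index=table.index,
        columns=table.columns,
    )
    out.attrs["totals"] = totals.loc[table.columns].to_dict()
    return out


def aggregate_genus(table: pd.DataFrame, taxonomy: Mapping[str, str] | pd.Series) -> pd.DataFrame:
    """Sum feature rows into genus rows using an ASV -> lineage map.

    Total mass per sample is conserved; ASVs without a genus land in
    ``"unclassified"``.
    """
    taxonomy = pd.Series(taxonomy)
    genera = [parse_genus(taxonomy.get(a)) for a in table.index]
    out = table.groupby(pd.Index(genera, name="genus"), sort=True).sum()
    return out


def genus_differential_abundance(
    genus_table: pd.DataFrame,
    groups: Mapping[str, str] | pd.Series,
    timepoints: Mapping[str, float] | pd.Series | None = None,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-genus two-sided permutation t-test between two groups, with
    Holm correction across genera within each timepoint.

    ``groups`` maps sample id -> group label (exactly two levels);
    ``timepoints`` optionally maps sample id -> timepoint, in which case
    the test is run separately within each timepoint (the Holm family is
    the set of genera at that timepoint). Copy-number values are permuted
    across samples 10,000 times by default.
    """
    groups = pd.Series(groups)
    levels = sorted(pd.unique(groups.loc[genus_table.columns]))
    if len(levels) != 2:
        raise ValueError("genus_differential_abundance needs exactly 2 groups")
    if timepoints is None:
        tp = pd.Series(0.0, index=genus_table.columns)
    else:
        tp = pd.Series(timepoints).loc[genus_table.columns]

    rng = np.random.default_rng(seed)
    rows = []
    for t_val in sorted(pd.unique(tp)):
        samples = [s for s in genus_table.columns if tp[s] == t_val]
        g = groups.loc[samples]
        a_samples = [s for s in samples if g[s] == levels[0]]
        b_samples = [s for s in samples if g[s] == levels[1]]
        tp_rows = []
        for genus in genus_table.index:
            x = genus_table.loc[genus, a_samples].to_numpy(dtype=float)
            y = genus_table.loc[genus, b_samples].to_numpy(dtype=float)
            sub_seed = int(rng.integers(0, 2**31 - 1))
            res: PermTestResult = permutation_t_test(x, y, n_perm=n_perm, seed=sub_seed)
            tp_rows.append(
                {
                    "genus": genus,
                    "timepoint": t_val,
                    "mean_" + str(levels[0]): float(np.mean(x)),
                    "mean_" + str(levels[1]): float(np.mean(y)),
                    "t": res.observed_t,
                    "p_raw": res.p_value,
                    "direction": (
                        f"{levels[0]}>{levels[1]}" if np.mean(x) > np.mean(y) else f"{levels[1]}>{levels[0]}"
                    ),
                }
            )
        sub = pd.DataFrame(tp_rows)
        sub["p_holm"] = holm_bonferroni(sub["p_raw"].to_numpy())
        rows.append(sub)
    return pd.concat(rows, ignore_index=True)


def community_permanova(
    table: pd.DataFrame,
    groups: Mapping[str, str] | pd.Series,
    n_perm: int = 999,
    seed: int | None = None,
) -> PermanovaResult:
    """PERMANOVA on Bray-Curtis dissimilarities of the (absolute) feature
    table; ``table`` is feature x sample, groups map sample -> label."""
    groups = pd.Series(groups)
    dm = bray_curtis(table.T)
    return permanova(dm, groups.loc[table.columns].to_numpy(), n_perm=n_perm, seed=seed)


def community_pcoa(table: pd.DataFrame):
    """Classical MDS (PCoA) ordination of the Bray-Curtis matrix; a
    plotting convenience returning skbio's OrdinationResults."""
    dm = bray_curtis(table.T)
    return _skbio_pcoa(dm, number_of_dimensions=2)
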