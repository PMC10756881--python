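"""Compartment-enrichment filter identifying metapleural-gland-secreted
proteins from iBAQ abundance tables.

Samples come from three compartments: the gland's atrium (the secreted
content), the secretory cells, and the hemolymph (circulating background).
A protein counts as a secretome hit if it is present in the atrium and
either absent from the hemolymph entirely (``atrium_only``) or on average
at least 1.5-fold more abundant in atrium than hemolymph (``enriched``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["SecretomeHit", "filter_secretome", "ibaq_percent"]


@dataclass(frozen=True)
class SecretomeHit:
    protein_id: str
    hit_class: str  # "atrium_only" | "enriched"
    mean_log2fc_atrium_vs_hemolymph: float  # inf for atrium_only
    n_atrium_detected: int
    mean_percent_ibaq_atrium: float


def _detected(v) -> bool:
    return pd.notna(v) and v > 0


def filter_secretome(
    table: pd.DataFrame,
    fold_threshold: float = 1.5,
    log_scale: bool = False,
) -> list[SecretomeHit]:
    """Apply the atrium-presence / hemolymph-enrichment filter cascade.

    ``table`` is tidy: protein_id, sample_id, compartment, ibaq (missing
    or zero iBAQ = not detected). Steps: (1) drop proteins not detected in
    any atrium sample; (2) proteins never detected in hemolymph are
    ``atrium_only`` hits regardless of abundance; (3) the rest are
    ``enriched`` hits iff mean atrium iBAQ / mean hemolymph iBAQ >=
    ``fold_threshold`` (inclusive). Means are over all replicates of the
    compartment with non-detected values as 0; ``log_scale=True`` compares
    means of log2 iBAQ over detected replicates instead.
    """
    if fold_threshold <= 0:
        raise ValueError("fold_threshold must be positive")
    atrium = table[table["compartment"] == "atrium"]
    hemo = table[table["compartment"] == "hemolymph"]
    if len(atrium) == 0 or len(hemo) == 0:
        raise ValueError("need at least one atrium and one hemolymph sample")
    n_atrium_samples = atrium["sample_id"].nunique()
    n_hemo_samples = hemo["sample_id"].nunique()

    pct = ibaq_percent(table)
    atrium_samples = sorted(pd.unique(atrium["sample_id"]))

    hits: list[SecretomeHit] = []
    for pid in sorted(pd.unique(table["protein_id"])):
        a_vals = atrium.loc[atrium["protein_id"] == pid, "ibaq"]
        a_det = a_vals[a_vals.map(_detected)]
        if len(a_det) == 0:
            continue  # step 1: absent from atrium
        h_vals = hemo.loc[hemo["protein_id"] == pid, "ibaq"]
        h_det = h_vals[h_vals.map(_detected)]
        mean_pct = float(
            np.nanmean(
                [pct.at[pid, s] if (pid in pct.index and s in pct.columns) else np.nan
                 for s in atrium_samples]
            )
        )
        if len(h_det) == 0:
            hits.append(
                SecretomeHit(pid, "atrium_only", np.inf, len(a_det), mean_pct)
            )
            continue
        if log_scale:
            log2fc = float(np.mean(np.log2(a_det)) - np.mean(np.log2(h_det)))
            keep = log2fc >= np.log2(fold_threshold)
        else:
            mean_a = float(a_det.sum()) / n_atrium_samples
            mean_h = float(h_det.sum()) / n_hemo_samples
            log2fc = float(np.log2(mean_a / mean_h))
            keep = mean_a / mean_h >= fold_threshold
        if keep:
            hits.append(SecretomeHit(pid, "enriched", log2fc, len(a_det), mean_pct))
    return hits


def ibaq_percent(table: pd.DataFrame) -> pd.DataFrame:
    """Per-protein percent of total iBAQ within each sample.

    Returns a protein x sample matrix whose columns sum to 100 over
    detected proteins (NaN = not detected in that sample).
    """
    wide = table.pivot_table(
        index="protein_id", columns="sample_id", values="ibaq", aggfunc="sum"
    )
    wide = wide.where(wide > 0)
    colsums = wide.sum(axis=0, skipna=True)
    return 100.0 * wide / colsums
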