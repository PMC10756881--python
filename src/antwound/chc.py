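"""Cuticular-hydrocarbon (CHC) profile summaries: compound-class relative
abundances, profile-level PERMANOVA, and per-class ANOVA/Tukey contrasts.

Profiles are consumed as already-integrated relative peak areas (fractions
summing to 1 per sample); compounds are grouped into alkanes, alkenes,
alkadienes and methyl-branched alkanes.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .statcore import PermanovaResult, anova_tukey, bray_curtis, permanova

__all__ = [
    "CHC_CLASSES",
    "class_relative_abundance",
    "profile_permanova",
    "class_anova",
]

CHC_CLASSES = ("alkane", "alkene", "alkadiene", "methyl_branched")


def _validate(profile: pd.DataFrame) -> None:
    required = {"sample_id", "compound_id", "compound_class", "rel_abund"}
    missing = required - set(profile.columns)
    if missing:
        raise ValueError(f"profile table missing columns: {sorted(missing)}")
    if (profile["rel_abund"] < 0).any():
        raise ValueError("negative relative abundances")
    sums = profile.groupby("sample_id")["rel_abund"].sum()
    off = sums[(sums - 1.0).abs() > 1e-6]
    if len(off):
        raise ValueError(f"per-sample abundances must sum to 1; offending: {list(off.index)}")


def class_relative_abundance(profile: pd.DataFrame) -> pd.DataFrame:
    """Class x sample fractions (member compounds summed; columns sum to 1)."""
    _validate(profile)
    return (
        profile.pivot_table(
            index="compound_class", columns="sample_id", values="rel_abund", aggfunc="sum"
        )
        .fillna(0.0)
    )


def profile_permanova(
    profile: pd.DataFrame,
    groups: Mapping[str, str] | pd.Series,
    n_perm: int = 999,
    seed: int | None = None,
) -> PermanovaResult:
    """PERMANOVA on Bray-Curtis dissimilarities of whole CHC profiles."""
    _validate(profile)
    wide = profile.pivot_table(
        index="sample_id", columns="compound_id", values="rel_abund", aggfunc="sum"
    ).fillna(0.0)
    groups = pd.Series(groups)
    dm = bray_curtis(wide)
    return permanova(dm, groups.loc[wide.index].to_numpy(), n_perm=n_perm, seed=seed)


def class_anova(
    profile: pd.DataFrame, groups: Mapping[str, str] | pd.Series
) -> pd.DataFrame:
    """Per-class one-way ANOVA + Tukey HSD of class fractions across
    groups; returns one row per (class, group pair)."""
    fracs = class_relative_abundance(profile)
    groups = pd.Series(groups)
    out = []
    for cls in fracs.index:
        vals = fracs.loc[cls]
        res = anova_tukey(vals.to_numpy(), groups.loc[vals.index].to_numpy())
        res.insert(0, "compound_class", cls)
        out.append(res)
    return pd.concat(out, ignore_index=True)
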