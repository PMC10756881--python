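"""Relative (delta-Cq) and absolute bacterial-load computation from qPCR
quantification-cycle tables, plus standard-curve efficiency estimation.

The relative bacterial load normalizes a target amplicon to the host 28S
reference: dCq = 2^(Cq_host - Cq_target). Absolute 16S copy numbers come
from a serial-dilution standard curve as n = E^(intercept - Cq), where E is
the per-cycle amplification efficiency (2 = perfect doubling) estimated
from the slope of Cq on log10 concentration: E = 10^(-1/slope).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .statcore import holm_bonferroni, welch_t

__all__ = [
    "StandardCurve",
    "DEFAULT_INTERCEPT",
    "DEFAULT_EFFICIENCIES",
    "delta_cq",
    "fit_standard_curve",
    "absolute_copies",
    "delta_cq_table",
    "load_contrasts",
]

#: Standard-curve intercept (cycles at log10 concentration 0) used for
#: absolute 16S quantification when no curve is supplied.
DEFAULT_INTERCEPT = 38.23

#: Per-primer amplification efficiencies estimated from 10x serial
#: dilutions: total-16S, Pseudomonas-specific, and host 28S primers.
DEFAULT_EFFICIENCIES = {
    "total_16s": 1.86,
    "pseudomonas": 2.00,
    "host_28s": 1.87,
}

#: Cq ceiling used to censor reactions that never amplified.
DEFAULT_CYCLE_CEILING = 45.0


@dataclass(frozen=True)
class StandardCurve:
    """Least-squares standard curve of Cq on log10 template concentration."""

    slope: float
    intercept: float
    efficiency: float
    r_squared: float


def delta_cq(cq_host, cq_target):
    """Relative target load 2^(cq_host - cq_target).

    Accepts scalars or arrays; missing (NaN) Cq values propagate as NaN
    rather than being coerced to zero load.
    """
    host = np.asarray(cq_host, dtype=float)
    target = np.asarray(cq_target, dtype=float)
    out = np.power(2.0, host - target)
    if out.ndim == 0:
        return float(out)
    return out


def fit_standard_curve(log10_dilution: Sequence[float], cq: Sequence[float]) -> StandardCurve:
    """Fit Cq = slope * log10(concentration) + intercept by OLS.

    The amplification efficiency is E = 10^(-1/slope); a nonnegative slope
    (no dilution signal) leaves E undefined and raises ``ValueError``.
    """
    x = np.asarray(log10_dilution, dtype=float)
    y = np.asarray(cq, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 dilution points")
    if np.any(np.diff(np.sort(x)) == 0):
        raise ValueError("dilution points must be distinct")
    fit = stats.linregress(x, y)
    if fit.slope >= 0:
        raise ValueError("efficiency undefined: nonnegative standard-curve slope")
    eff = 10.0 ** (-1.0 / fit.slope)
    return StandardCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        efficiency=float(eff),
        r_squared=float(fit.rvalue**2),
    )


def absolute_copies(cq, efficiency: float | StandardCurve = 2.0, intercept: float | None = None):
    """Absolute copy number n = E^(intercept - cq).

    ``efficiency`` may be a :class:`StandardCurve` (its own intercept is
    used unless overridden) or a bare efficiency in (1, 2]; the intercept
    defaults to ``DEFAULT_INTERCEPT`` (38.23).
    """
    if isinstance(efficiency, StandardCurve):
        if intercept is None:
            intercept = efficiency.intercept
        eff = efficiency.efficiency
    else:
        eff = float(efficiency)
    if intercept is None:
        intercept = DEFAULT_INTERCEPT
    if not (1.0 < eff <= 2.0 + 1e-9):
        raise ValueError("efficiency must lie in (1, 2]")
    cq_arr = np.asarray(cq, dtype=float)
    out = np.power(eff, intercept - cq_arr)
    if out.ndim == 0:
        return float(out)
    return out


def _tidy_to_wide(table: pd.DataFrame, host_target: str) -> pd.DataFrame:
    """Collapse a tidy Cq table (one row per sample x target, technical
    replicates averaged) into one row per sample with per-target Cq columns."""
    required = {"sample_id", "target", "cq"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"Cq table is missing columns: {sorted(missing)}")
    meta_cols = [
        c for c in ("treatment", "location", "timepoint_h", "colony") if c in table.columns
    ]
    mean_cq = (
        table.groupby(["sample_id", "target"], sort=False)["cq"].mean().unstack("target")
    )
    if host_target not in mean_cq.columns:
        raise ValueError(f"host target {host_target!r} not present in table")
    meta = table.drop_duplicates("sample_id").set_index("sample_id")[meta_cols]
    return mean_cq.join(meta)


def delta_cq_table(
    table: pd.DataFrame,
    target: str,
    host_target: str = "host_28s",
    cycle_ceiling: float = DEFAULT_CYCLE_CEILING,
) -> pd.DataFrame:
    """Per-sample relative load of ``target`` normalized to the host gene.

    Technical replicates are averaged per target before the ratio. Missing
    target Cq (no amplification) is censored at ``cycle_ceiling`` cycles;
    missing host Cq leaves the sample's load as NaN.
    """
    wide = _tidy_to_wide(table, host_target)
    if target not in wide.columns:
        raise ValueError(f"target {target!r} not present in table")
    cq_t = wide[target].fillna(cycle_ceiling)
    load = delta_cq(wide[host_target].to_numpy(), cq_t.to_numpy())
    out = wide.drop(columns=[c for c in wide.columns if c in (target, host_target)])
    out = out.copy()
    out["cq_host"] = wide[host_target]
    out["cq_target"] = cq_t
    out["rel_load"] = load
    out["log2_rel_load"] = np.log2(load)
    return out.reset_index()


def load_contrasts(
    table: pd.DataFrame,
    target: str,
    grouping: Sequence[str] = ("treatment", "timepoint_h"),
    host_target: str = "host_28s",
    cycle_ceiling: float = DEFAULT_CYCLE_CEILING,
) -> pd.DataFrame:
    """Pairwise fold changes in relative load between design cells.

    Cells are the distinct combinations of the ``grouping`` columns. Fold
    changes are ratios of geometric-mean relative loads (arithmetic means
    of log2 dCq); significance is a Welch t-test on the per-sample log2
    values, Holm-corrected across all pairwise contrasts.
    """
    grouping = list(grouping)
    loads = delta_cq_table(table, target, host_target, cycle_ceiling)
    cells = {}
    for key, sub in loads.groupby(grouping, sort=False):
        if not isinstance(key, tuple):
            key = (key,)
        if len(sub) < 2:
            raise ValueError(f"cell {key} has fewer than 2 samples")
        cells[key] = sub["log2_rel_load"].to_numpy()

    rows = []
    for (k1, v1), (k2, v2) in itertools.combinations(cells.items(), 2):
        t, df, p = welch_t(v1, v2)
        rows.append(
            {
                "cell_a": "/".join(map(str, k1)),
                "cell_b": "/".join(map(str, k2)),
                "fold_a_vs_b": float(2.0 ** (np.mean(v1) - np.mean(v2))),
                "t": t,
                "df": df,
                "p_raw": p,
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["p_holm"] = holm_bonferroni(out["p_raw"].to_numpy())
    return out
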