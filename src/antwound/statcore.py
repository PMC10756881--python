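"""Shared statistical engine: resampling tests, multiple-testing correction,
dissimilarity and PERMANOVA machinery used by all downstream stages.

The permutation two-sample t-test and the one-factor PERMANOVA are
implemented here directly (they are the core resampling procedures of the
pipeline); classical tests (Welch t, Mann-Whitney U, ANOVA + Tukey HSD) and
the Holm step-down correction delegate to scipy / statsmodels.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PermTestResult",
    "PermanovaResult",
    "holm_bonferroni",
    "permutation_t_test",
    "permanova",
    "bray_curtis",
    "welch_t",
    "mann_whitney_u",
    "anova_tukey",
]


@dataclass(frozen=True)
class PermTestResult:
    """Outcome of a two-sided permutation two-sample t-test.

    ``p_value`` counts the identity arrangement toward the null
    distribution, so it is bounded below by ``1/(n_permutations + 1)`` in
    sampled mode and by ``1/n_permutations`` in exhaustive mode.
    """

    observed_t: float
    p_value: float
    n_permutations: int
    seed: int | None = None
    exhaustive: bool = False


@dataclass(frozen=True)
class PermanovaResult:
    """One-factor PERMANOVA (Anderson-style) on a distance matrix."""

    pseudo_F: float
    r_squared: float
    p_value: float
    df_between: int
    df_within: int
    n_permutations: int
    ss_between: float
    ss_within: float
    ss_total: float


def holm_bonferroni(pvals: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted p-values, in the input order, capped at 1.

    An empty input yields an empty array; values outside [0, 1] raise
    ``ValueError``.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.array([], dtype=float)
    if np.any(np.isnan(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


def _welch_t_stat(x: np.ndarray, y: np.ndarray) -> float:
    """Welch t statistic; 0 for identical degenerate groups, +/-inf when the
    means differ but both variances vanish."""
    n1, n2 = len(x), len(y)
    v1 = x.var(ddof=1)
    v2 = y.var(ddof=1)
    num = x.mean() - y.mean()
    den = math.sqrt(v1 / n1 + v2 / n2)
    if den == 0.0:
        return 0.0 if num == 0.0 else math.copysign(math.inf, num)
    return num / den


def _pooled_t_stat(x: np.ndarray, y: np.ndarray) -> float:
    n1, n2 = len(x), len(y)
    v1 = x.var(ddof=1)
    v2 = y.var(ddof=1)
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    num = x.mean() - y.mean()
    den = math.sqrt(sp2 * (1 / n1 + 1 / n2))
    if den == 0.0:
        return 0.0 if num == 0.0 else math.copysign(math.inf, num)
    return num / den


def _batch_t(left: np.ndarray, right: np.ndarray, equal_var: bool) -> np.ndarray:
    """Row-wise two-sample t statistics for permutation batches.

    ``left``/``right`` have shape (batch, n1) and (batch, n2). Degenerate
    rows (zero pooled standard error) map to 0 when the means agree and
    +/-inf otherwise, matching the scalar path.
    """
    n1 = left.shape[1]
    n2 = right.shape[1]
    m1 = left.mean(axis=1)
    m2 = right.mean(axis=1)
    v1 = left.var(axis=1, ddof=1)
    v2 = right.var(axis=1, ddof=1)
    if equal_var:
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        den = np.sqrt(sp2 * (1 / n1 + 1 / n2))
    else:
        den = np.sqrt(v1 / n1 + v2 / n2)
    num = m1 - m2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = num / den
        t = np.where(den == 0.0, np.where(num == 0.0, 0.0, np.sign(num) * np.inf), t)
    return t


def permutation_t_test(
    x: Sequence[float],
    y: Sequence[float],
    n_perm: int = 10_000,
    seed: int | None = None,
    exhaustive: bool = False,
    equal_var: bool = False,
) -> PermTestResult:
    """Two-sided permutation two-sample t-test.

    Group labels are permuted and the proportion of permutation statistics
    with ``|t| >= |t_obs|`` is reported. In sampled mode the identity
    arrangement is added to ``n_perm`` random permutations, so p is at
    least ``1/(n_perm + 1)``. With ``exhaustive=True`` all
    ``C(n1+n2, n1)`` label assignments are enumerated instead (which
    include the identity). The statistic is Welch's t by default
    (``equal_var=True`` switches to the pooled version).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 observations")
    pooled = np.concatenate([x, y])
    n1 = len(x)
    n = len(pooled)

    stat = _pooled_t_stat if equal_var else _welch_t_stat
    t_obs = stat(x, y)

    if pooled.var() == 0.0:
        warnings.warn("constant pooled data: permutation p-value is 1", stacklevel=2)
        n_eval = math.comb(n, n1) if exhaustive else n_perm + 1
        return PermTestResult(0.0, 1.0, n_eval, seed, exhaustive)

    abs_obs = abs(t_obs)
    if exhaustive:
        hits = 0
        total = 0
        for combo in combinations(range(n), n1):
            sel = np.zeros(n, dtype=bool)
            sel[list(combo)] = True
            t_p = stat(pooled[sel], pooled[~sel])
            # >= with a relative guard against roundoff on re-partitions
            if abs(t_p) >= abs_obs - 1e-12 * max(1.0, abs_obs):
                hits += 1
            total += 1
        return PermTestResult(float(t_obs), hits / total, total, seed, True)

    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    batch = np.tile(pooled, (n_perm, 1))
    batch = rng.permuted(batch, axis=1)
    t_perm = _batch_t(batch[:, :n1], batch[:, n1:], equal_var)
    hits = 1 + int(np.sum(np.abs(t_perm) >= abs_obs - 1e-12 * max(1.0, abs_obs)))
    return PermTestResult(float(t_obs), hits / (n_perm + 1), n_perm + 1, seed, False)


def bray_curtis(abund, ids: Sequence[str] | None = None) -> DistanceMatrix:
    """Bray-Curtis dissimilarity matrix over the rows (samples) of a
    nonnegative sample x feature matrix.

    d_ij = sum_k |a_ik - a_jk| / sum_k (a_ik + a_jk), in [0, 1]. An
    all-zero sample row makes the dissimilarity undefined and raises a
    ``ValueError`` naming the sample.
    """
    if isinstance(abund, pd.DataFrame):
        values = abund.to_numpy(dtype=float)
        if ids is None:
            ids = [str(i) for i in abund.index]
    else:
        values = np.asarray(abund, dtype=float)
    if ids is None:
        ids = [str(i) for i in range(values.shape[0])]
    if np.any(values < 0):
        raise ValueError("negative abundances are not allowed")
    rowsums = values.sum(axis=1)
    if np.any(rowsums == 0):
        bad = [str(ids[i]) for i in np.flatnonzero(rowsums == 0)]
        raise ValueError(f"all-zero sample row(s): {', '.join(bad)}")
    d = squareform(pdist(values, metric="braycurtis"))
    return DistanceMatrix(d, ids=list(map(str, ids)))


def _permanova_ss(d2: np.ndarray, groups: np.ndarray):
    """Sums of squares from a squared-distance matrix and group labels."""
    n = d2.shape[0]
    iu = np.triu_indices(n, k=1)
    ss_total = d2[iu].sum() / n
    ss_within = 0.0
    for g in np.unique(groups):
        members = np.flatnonzero(groups == g)
        if len(members) > 1:
            sub = d2[np.ix_(members, members)]
            ss_within += sub[np.triu_indices(len(members), k=1)].sum() / len(members)
    return ss_total, ss_within


def permanova(
    d: DistanceMatrix,
    groups: Sequence,
    n_perm: int = 999,
    seed: int | None = None,
) -> PermanovaResult:
    """One-factor PERMANOVA on a distance matrix.

    SS_total = (1/N) sum_{i<j} d_ij^2 and SS_within sums the analogous
    per-group quantities; pseudo-F = (SS_b/(a-1)) / (SS_w/(N-a)). The
    p-value permutes group labels, counting the identity arrangement, so
    it is never 0. A degenerate zero SS_within yields pseudo-F = +inf.
    """
    groups = np.asarray(groups)
    dm = d.data if isinstance(d, DistanceMatrix) else np.asarray(d, dtype=float)
    n = dm.shape[0]
    if len(groups) != n:
        raise ValueError("group labels must match the distance matrix size")
    levels, counts = np.unique(groups, return_counts=True)
    a = len(levels)
    if a < 2:
        raise ValueError("PERMANOVA needs at least 2 groups")

    d2 = dm**2
    ss_total, ss_within = _permanova_ss(d2, groups)
    ss_between = ss_total - ss_within
    df_b = a - 1
    df_w = n - a

    def f_stat(ssw: float) -> float:
        if ssw <= 0.0:
            return math.inf
        return ((ss_total - ssw) / df_b) / (ssw / df_w)

    f_obs = f_stat(ss_within)
    r2 = ss_between / ss_total if ss_total > 0 else 0.0

    rng = np.random.default_rng(seed)
    hits = 1  # identity arrangement
    for _ in range(n_perm):
        perm = rng.permutation(groups)
        _, ssw_p = _permanova_ss(d2, perm)
        if f_stat(ssw_p) >= f_obs - 1e-12 * max(1.0, abs(f_obs) if math.isfinite(f_obs) else 1.0):
            hits += 1
    p = hits / (n_perm + 1)
    return PermanovaResult(
        pseudo_F=float(f_obs),
        r_squared=float(r2),
        p_value=p,
        df_between=df_b,
        df_within=df_w,
        n_permutations=n_perm + 1,
        ss_between=float(ss_between),
        ss_within=float(ss_within),
        ss_total=float(ss_total),
    )


def welch_t(x: Sequence[float], y: Sequence[float]):
    """Welch two-sample t-test: returns (t, Satterthwaite df, two-sided p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.var(ddof=1) == 0.0 and y.var(ddof=1) == 0.0:
        if x.mean() == y.mean():
            return 0.0, float(len(x) + len(y) - 2), 1.0
    res = stats.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def mann_whitney_u(x: Sequence[float], y: Sequence[float]):
    """Two-sided Mann-Whitney U test with tie correction: returns (U, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.array_equal(np.sort(x), np.sort(y)):
        # identical samples: U is its null mean, no evidence either way
        return float(len(x) * len(y) / 2), 1.0
    res = stats.mannwhitneyu(x, y, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def anova_tukey(values: Sequence[float], groups: Sequence) -> pd.DataFrame:
    """One-way ANOVA followed by Tukey HSD (Tukey-Kramer for unbalanced
    layouts), returning one row per group pair with the adjusted p-value.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if len(values) != len(groups):
        raise ValueError("values and groups must have equal length")
    res = pairwise_tukeyhsd(values, groups)
    frame = pd.DataFrame(
        res.summary().data[1:], columns=[str(c) for c in res.summary().data[0]]
    )
    out = pd.DataFrame(
        {
            "group1": frame["group1"],
            "group2": frame["group2"],
            "mean_diff": frame["meandiff"].astype(float),
            "p_adj": res.pvalues,
        }
    )
    return out
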