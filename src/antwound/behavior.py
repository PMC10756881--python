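"""Behavioral event-log analysis for the 24-h wound-care observations.

Care events are binned into 144 ten-minute intervals per ant. The
probability of receiving care over time is modeled per group with a
penalized cubic B-spline logistic regression (a binomial smoother in the
spirit of a GAM): the bin indicator is regressed on time with a
second-difference penalty on the spline coefficients, the smoothing
parameter is chosen by generalized cross-validation, and a pointwise 95%
Wald band is formed on the link scale and mapped through the inverse
logit. Group differences are screened bin-wise on the link scale and
contiguous significant bins are merged into time intervals.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline

from .statcore import welch_t

__all__ = [
    "N_BINS",
    "BIN_S",
    "SmootherFit",
    "bin_events",
    "fit_care_smoother",
    "significant_intervals",
    "mg_care_fraction",
    "care_duration_test",
]

BIN_S = 600
N_BINS = 144  # 24 h of 10-min bins
HORIZON_S = BIN_S * N_BINS


def bin_events(log: pd.DataFrame, event_type: str | None = None) -> pd.DataFrame:
    """Binary ant x bin matrix: 1 iff any event overlaps the 10-min bin.

    An event occupying ``[start_s, start_s + duration_s)`` marks every bin
    it overlaps, so an event spanning a bin boundary marks both bins.
    ``event_type`` restricts to one behavior class (e.g. ``"mg_care"``).
    Rows are ant ids; ants present in the log but with no qualifying
    events get all-zero rows.
    """
    sub = log if event_type is None else log[log["event_type"] == event_type]
    ants = sorted(pd.unique(log["ant_id"]))
    mat = pd.DataFrame(
        np.zeros((len(ants), N_BINS), dtype=int),
        index=pd.Index(ants, name="ant_id"),
        columns=range(N_BINS),
    )
    for row in sub.itertuples():
        start = float(row.event_start_s)
        dur = float(row.duration_s)
        if dur <= 0:
            raise ValueError(f"nonpositive duration for ant {row.ant_id}")
        first = int(start // BIN_S)
        # last bin whose interval [600b, 600(b+1)) intersects [start, start+dur)
        last = int(math.ceil((start + dur) / BIN_S)) - 1
        first = max(first, 0)
        last = min(last, N_BINS - 1)
        if first <= last:
            mat.loc[row.ant_id, first:last] = 1
    return mat


@dataclass(frozen=True)
class SmootherFit:
    """Penalized-spline logistic fit of care probability over time."""

    times_h: np.ndarray  # bin midpoints, hours
    prob: np.ndarray
    lo: np.ndarray
    hi: np.ndarray
    eta: np.ndarray  # linear predictor at bin midpoints
    eta_se: np.ndarray
    lam: float
    basis_dim: int
    label: str = ""


def _bspline_design(x: np.ndarray, k: int, degree: int = 3, domain=(0.0, 24.0)) -> np.ndarray:
    lo, hi = domain
    n_interior = k - degree - 1
    interior = np.linspace(lo, hi, n_interior + 2)[1:-1]
    knots = np.r_[[lo] * (degree + 1), interior, [hi] * (degree + 1)]
    return BSpline.design_matrix(x, knots, degree).toarray()


def _second_diff_penalty(k: int) -> np.ndarray:
    d = np.diff(np.eye(k), n=2, axis=0)
    return d.T @ d


def _pirls(
    b: np.ndarray, y: np.ndarray, pen: np.ndarray, lam: float, max_iter: int = 100
):
    """Penalized IRLS for Bernoulli-logit; returns (beta, cov, edf, deviance)."""
    n, k = b.shape
    mu = np.clip((y + 0.5) / 2.0, 0.05, 0.95)
    eta = np.log(mu / (1 - mu))
    beta = np.zeros(k)
    dev_old = np.inf
    a = None
    for _ in range(max_iter):
        w = mu * (1 - mu)
        z = eta + (y - mu) / w
        bw = b * w[:, None]
        a = b.T @ bw + lam * pen
        beta = np.linalg.solve(a, bw.T @ z)
        eta = b @ beta
        eta = np.clip(eta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        mu = np.clip(mu, 1e-10, 1 - 1e-10)
        dev = -2.0 * np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu))
        if abs(dev_old - dev) < 1e-8 * (abs(dev) + 1e-8):
            dev_old = dev
            break
        dev_old = dev
    w = mu * (1 - mu)
    a = b.T @ (b * w[:, None]) + lam * pen
    a_inv = np.linalg.inv(a)
    edf = float(np.trace(a_inv @ (b.T @ (b * w[:, None]))))
    cov = a_inv  # Bayesian-style posterior covariance (mgcv convention)
    return beta, cov, edf, dev_old


def fit_care_smoother(
    binned: pd.DataFrame,
    basis_dim: int = 20,
    lam: float | None = None,
    label: str = "",
) -> SmootherFit:
    """Fit the per-group care-probability smoother from a binary ant x bin
    matrix (all ants in the matrix form one group, each bin of each ant a
    Bernoulli trial).

    ``lam=None`` selects the smoothing parameter by GCV over a log-spaced
    grid; passing a value fixes it. An all-zero or all-one response falls
    back to a constant fit with a warning (complete-separation guard).
    """
    if binned.shape[0] < 1:
        raise ValueError("need at least one individual")
    y = binned.to_numpy(dtype=float).ravel()
    mids_h = (np.arange(N_BINS) + 0.5) * BIN_S / 3600.0
    x = np.tile(mids_h, binned.shape[0])
    grid_eta_x = mids_h

    if y.min() == y.max():
        warnings.warn("degenerate response (all 0 or all 1): constant fit", stacklevel=2)
        n = len(y)
        phat = (y.sum() + 0.5) / (n + 1.0)
        eta = math.log(phat / (1 - phat))
        se = 1.0 / math.sqrt(n * phat * (1 - phat))
        eta_arr = np.full(N_BINS, eta)
        se_arr = np.full(N_BINS, se)
        lo = 1 / (1 + np.exp(-(eta_arr - 1.96 * se_arr)))
        hi = 1 / (1 + np.exp(-(eta_arr + 1.96 * se_arr)))
        return SmootherFit(
            times_h=grid_eta_x,
            prob=np.full(N_BINS, phat),
            lo=lo,
            hi=hi,
            eta=eta_arr,
            eta_se=se_arr,
            lam=math.inf,
            basis_dim=basis_dim,
            label=label,
        )

    b = _bspline_design(x, basis_dim)
    pen = _second_diff_penalty(basis_dim)
    n = len(y)

    if lam is None:
        grid = np.logspace(-3, 6, 19)
        best = (np.inf, None)
        for lam_c in grid:
            _, _, edf, dev = _pirls(b, y, pen, lam_c)
            gcv = n * dev / (n - edf) ** 2
            if gcv < best[0]:
                best = (gcv, lam_c)
        lam = float(best[1])

    beta, cov, _, _ = _pirls(b, y, pen, lam)
    bg = _bspline_design(grid_eta_x, basis_dim)
    eta = bg @ beta
    eta_se = np.sqrt(np.einsum("ij,jk,ik->i", bg, cov, bg))
    prob = 1.0 / (1.0 + np.exp(-eta))
    lo = 1.0 / (1.0 + np.exp(-(eta - 1.96 * eta_se)))
    hi = 1.0 / (1.0 + np.exp(-(eta + 1.96 * eta_se)))
    return SmootherFit(
        times_h=grid_eta_x,
        prob=prob,
        lo=lo,
        hi=hi,
        eta=eta,
        eta_se=eta_se,
        lam=float(lam),
        basis_dim=basis_dim,
        label=label,
    )


def significant_intervals(
    fit_a: SmootherFit,
    fit_b: SmootherFit,
    alpha: float = 0.05,
    direction: str = "two-sided",
) -> list[tuple[float, float]]:
    """Time intervals (hours) where the two groups' care probabilities
    differ significantly.

    Bin-wise Wald test of the link-scale difference (independent groups),
    contiguous rejected bins merged. ``direction`` is ``"two-sided"`` or
    ``"a>b"`` (one-sided elevation of group a).
    """
    from scipy.stats import norm

    if not np.array_equal(fit_a.times_h, fit_b.times_h):
        raise ValueError("fits must share the same time grid")
    diff = fit_a.eta - fit_b.eta
    se = np.sqrt(fit_a.eta_se**2 + fit_b.eta_se**2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, diff / se, 0.0)
    if direction == "two-sided":
        reject = 2 * norm.sf(np.abs(z)) < alpha
    elif direction == "a>b":
        reject = norm.sf(z) < alpha
    else:
        raise ValueError("direction must be 'two-sided' or 'a>b'")

    intervals: list[tuple[float, float]] = []
    width_h = BIN_S / 3600.0
    start = None
    for i, r in enumerate(reject):
        edge_lo = fit_a.times_h[i] - width_h / 2
        edge_hi = fit_a.times_h[i] + width_h / 2
        if r and start is None:
            start = edge_lo
        if not r and start is not None:
            intervals.append((start, fit_a.times_h[i - 1] + width_h / 2))
            start = None
    if start is not None:
        intervals.append((start, fit_a.times_h[-1] + width_h / 2))
    return intervals


def mg_care_fraction(log: pd.DataFrame) -> tuple[int, int, float]:
    """MG-care share of all wound-care interactions.

    Returns (count_mg, count_total, percent) where MG-care events are a
    subset of the total and the percent is rounded half-up to one decimal
    (43 of 411 -> 10.5).
    """
    count_total = len(log)
    count_mg = int((log["event_type"] == "mg_care").sum())
    if count_total == 0:
        raise ValueError("empty behavior log")
    pct = Decimal(100 * count_mg) / Decimal(count_total)
    pct = float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))
    return count_mg, count_total, pct


def care_duration_test(log: pd.DataFrame) -> dict:
    """Welch t-test of per-event durations, MG care vs plain care.

    Returns group means/sds and the test; needs at least two events per
    class.
    """
    mg = log.loc[log["event_type"] == "mg_care", "duration_s"].to_numpy(dtype=float)
    plain = log.loc[log["event_type"] == "care", "duration_s"].to_numpy(dtype=float)
    if len(mg) < 2 or len(plain) < 2:
        raise ValueError("insufficient data: need >=2 events per care class")
    t, df, p = welch_t(mg, plain)
    return {
        "mean_mg": float(mg.mean()),
        "sd_mg": float(mg.std(ddof=1)),
        "mean_care": float(plain.mean()),
        "sd_care": float(plain.std(ddof=1)),
        "t": t,
        "df": df,
        "p": p,
        "n_mg": len(mg),
        "n_care": len(plain),
    }
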