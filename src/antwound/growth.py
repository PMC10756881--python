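"""Logistic growth fitting of OD600 microplate curves and
growth-inhibition quantification for the antimicrobial assay.

The population model is N(t) = K / (1 + ((K - N0)/N0) * exp(-r t)) with
carrying capacity K, initial size N0 and intrinsic growth rate r (the rate
absent any resource limitation). Per-well fits use nonlinear least squares
with multi-start initialization; inhibition is the percent reduction of r
in treated wells relative to control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .statcore import mann_whitney_u

__all__ = [
    "GrowthFit",
    "logistic_model",
    "fit_logistic",
    "growth_inhibition",
    "subtract_blank",
    "fit_plate",
    "compare_growth_rates",
]


@dataclass(frozen=True)
class GrowthFit:
    """Least-squares logistic fit of one well."""

    r: float  # per hour
    K: float  # OD units
    N0: float  # OD units
    rss: float
    converged: bool


def logistic_model(t_h, K, N0, r):
    """Logistic trajectory N(t) at times ``t_h`` (hours)."""
    t_h = np.asarray(t_h, dtype=float)
    return K / (1.0 + ((K - N0) / N0) * np.exp(-r * t_h))


class GrowthFitError(RuntimeError):
    """Raised when a well cannot be fit; carries the best-so-far fit."""

    def __init__(self, message: str, best: GrowthFit | None = None):
        super().__init__(message)
        self.best = best


def fit_logistic(time_h, od, n_starts: int = 5, seed: int = 0) -> GrowthFit:
    """Fit the logistic model to one OD trajectory.

    Initialization takes N0 from the first reading, K from the maximum,
    and r from the log-slope of the early (sub-K/2) phase, with jittered
    restarts; the best (lowest-RSS) converged solution is returned. A flat
    trajectory raises ``GrowthFitError("no growth detected")``.
    """
    t = np.asarray(time_h, dtype=float)
    y = np.asarray(od, dtype=float)
    if len(t) < 6:
        raise ValueError("need at least 6 timepoints")
    if np.ptp(y) < 1e-6 or y.max() <= 0:
        raise GrowthFitError("no growth detected")

    n0_init = max(float(y[0]), 1e-6)
    k_init = max(float(y.max()), n0_init * 1.01)
    # early-phase exponential slope
    early = y < k_init / 2
    r_init = 0.5
    if early.sum() >= 3:
        ylog = np.log(np.clip(y[early], 1e-9, None))
        slope = np.polyfit(t[early], ylog, 1)[0]
        if slope > 0:
            r_init = float(slope)

    def resid(theta):
        k, n0, r = theta
        return logistic_model(t, k, n0, r) - y

    rng = np.random.default_rng(seed)
    best = None
    lb = [1e-9, 1e-9, 0.0]
    ub = [np.inf, np.inf, np.inf]
    for i in range(n_starts):
        jitter = np.ones(3) if i == 0 else rng.lognormal(0.0, 0.3, size=3)
        x0 = np.array([k_init, n0_init, r_init]) * jitter
        x0 = np.clip(x0, lb, None)
        try:
            sol = least_squares(resid, x0, bounds=(lb, ub), xtol=1e-12, ftol=1e-12)
        except Exception:
            continue
        rss = float(np.sum(sol.fun**2))
        fit = GrowthFit(
            r=float(sol.x[2]), K=float(sol.x[0]), N0=float(sol.x[1]),
            rss=rss, converged=bool(sol.status > 0),
        )
        if best is None or rss < best.rss:
            best = fit
    if best is None or not best.converged:
        raise GrowthFitError("logistic fit did not converge", best=best)
    return best


def growth_inhibition(r_control: float, r_treat: float) -> float:
    """Percent reduction of the intrinsic growth rate:
    100 * (r_control - r_treat) / r_control."""
    if r_control <= 0:
        raise ValueError("control growth rate must be positive")
    return 100.0 * (r_control - r_treat) / r_control


def subtract_blank(plate: pd.DataFrame) -> pd.DataFrame:
    """Subtract the mean blank trajectory from every non-blank well.

    ``plate`` is tidy: well_id, condition, time_min, od600. Corrected OD
    is clipped at 0. Plates without blank wells pass through unchanged
    with a warning.
    """
    blanks = plate[plate["condition"] == "blank"]
    out = plate[plate["condition"] != "blank"].copy()
    if len(blanks) == 0:
        warnings.warn("no blank wells: OD used uncorrected", stacklevel=2)
        return out
    blank_mean = blanks.groupby("time_min")["od600"].mean()
    out["od600"] = (
        out["od600"].to_numpy() - blank_mean.reindex(out["time_min"]).to_numpy()
    ).clip(min=0.0)
    return out


def fit_plate(plate: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Blank-correct and fit every well; returns per-well fit parameters."""
    corrected = subtract_blank(plate)
    rows = []
    for (well, cond), sub in corrected.groupby(["well_id", "condition"], sort=False):
        t_h = sub["time_min"].to_numpy(dtype=float) / 60.0
        fit = fit_logistic(t_h, sub["od600"].to_numpy(dtype=float), seed=seed)
        rows.append(
            {"well_id": well, "condition": cond, "r": fit.r, "K": fit.K,
             "N0": fit.N0, "rss": fit.rss}
        )
    return pd.DataFrame(rows)


def compare_growth_rates(
    fits: pd.DataFrame, control: str = "control", treatment: str = "mg"
) -> dict:
    """Mann-Whitney U comparison of per-well growth rates, plus the
    percent inhibition of the treated median rate relative to control."""
    r_c = fits.loc[fits["condition"] == control, "r"].to_numpy(dtype=float)
    r_t = fits.loc[fits["condition"] == treatment, "r"].to_numpy(dtype=float)
    if len(r_c) == 0 or len(r_t) == 0:
        raise ValueError("both conditions need fitted wells")
    u, p = mann_whitney_u(r_c, r_t)
    return {
        "U": u,
        "p": p,
        "median_r_control": float(np.median(r_c)),
        "median_r_treat": float(np.median(r_t)),
        "inhibition_pct": growth_inhibition(float(np.median(r_c)), float(np.median(r_t))),
        "n_control": len(r_c),
        "n_treat": len(r_t),
    }
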