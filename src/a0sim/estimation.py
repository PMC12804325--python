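"""A0 threshold estimation from simulated margin records.

The A0 threshold is the observed MAM at which a fitted logistic model
of true coverage, ``P(MAM_true > 0 | MAM_observed = x)``, reaches a
target probability (99% by default):

    logit P = beta0 + beta1 * x,   x_A0 = (logit(p) - beta0) / beta1.

The companion reliability statistic is the empirical coverage
probability among records whose observed MAM meets the conventional
5 mm rule, ``P(MAM_true > 0 | MAM_observed >= 5)``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "A0Estimate",
    "fit_coverage_curve",
    "solve_a0",
    "coverage_prob_at",
    "filter_registration",
    "estimate_a0",
]

#: |beta1| beyond which an ML "fit" is treated as (quasi-)separated:
#: a 1 mm change in observed MAM would move the odds by > e^50.
_SEPARATION_SLOPE = 50.0


@dataclass(frozen=True)
class A0Estimate:
    """Fitted coverage curve, A0 threshold and 5-mm reliability."""

    beta0: float
    beta1: float
    x_a0_mm: float
    p_coverage_at_5mm: float
    n_used: int
    n_excluded: int = 0
    p_target: float = 0.99
    separation_fallback: bool = False
    ridge_penalty: float = 0.0
    beta_se: tuple[float, float] = (float("nan"), float("nan"))

    @property
    def x_a0_reported(self) -> float:
        """Threshold rounded to the 0.1 mm reporting precision."""
        return round(self.x_a0_mm, 1)

    def predict(self, x) -> np.ndarray:
        """Fitted coverage probability at observed MAM ``x`` (mm)."""
        x = np.asarray(x, dtype=float)
        return 1.0 / (1.0 + np.exp(-(self.beta0 + self.beta1 * x)))

    def to_dict(self) -> dict:
        return {
            "beta0": self.beta0,
            "beta1": self.beta1,
            "x_a0_mm": self.x_a0_mm,
            "p_coverage_at_5mm": self.p_coverage_at_5mm,
            "n_used": self.n_used,
            "n_excluded": self.n_excluded,
            "p_target": self.p_target,
            "separation_fallback": self.separation_fallback,
            "ridge_penalty": self.ridge_penalty,
        }


def solve_a0(beta0: float, beta1: float, p_target: float = 0.99) -> float:
    """Observed MAM where the fitted sigmoid crosses ``p_target``."""
    if not 0.0 < p_target < 1.0:
        raise ValueError("p_target must be in (0, 1)")
    if not beta1 > 0:
        raise ValueError(f"coverage slope must be positive, got beta1={beta1}")
    return (math.log(p_target / (1.0 - p_target)) - beta0) / beta1


def _ridge_logit(x: np.ndarray, y: np.ndarray, alpha: float) -> np.ndarray:
    """Newton-IRLS logistic fit with a small L2 penalty (intercept included)."""
    X = np.column_stack([np.ones_like(x), x])
    beta = np.zeros(2)
    for _ in range(100):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1.0 - p) + 1e-12
        H = X.T @ (X * w[:, None]) + alpha * np.eye(2)
        g = X.T @ (y - p) - alpha * beta
        step = np.linalg.solve(H, g)
        beta = beta + step
        if np.abs(step).max() < 1e-10:
            break
    return beta


def fit_coverage_curve(
    mam_observed, covered_true, ridge_penalty: float = 0.0
):
    """Maximum-likelihood logistic fit of coverage on observed MAM.

    Returns ``(beta0, beta1, info)`` where ``info`` carries the standard
    errors and a ``separated`` flag.  With ``ridge_penalty > 0`` a small
    L2 penalty stabilizes near-separated data (recorded in the output).
    """
    x = np.asarray(mam_observed, dtype=float)
    y = np.asarray(covered_true, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 records to fit")
    if y.min() == y.max():
        raise ValueError(
            "all outcomes identical (all covered or all uncovered); "
            "no threshold is definable"
        )
    info: dict = {"separated": False, "bse": (float("nan"), float("nan"))}
    if ridge_penalty > 0:
        b0, b1 = _ridge_logit(x, y, ridge_penalty)
        return float(b0), float(b1), info
    X = sm.add_constant(x)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        b0, b1 = res.params
        info["bse"] = tuple(float(s) for s in res.bse)
        info["sm_results"] = res
        if not np.isfinite([b0, b1]).all() or abs(b1) > _SEPARATION_SLOPE:
            info["separated"] = True
    except Exception:  # PerfectSeparationError and numerical failures
        info["separated"] = True
        b0, b1 = float("nan"), float("nan")
    return float(b0), float(b1), info


def _binned_threshold(
    x: np.ndarray, y: np.ndarray, p_target: float, bin_mm: float = 0.5
) -> float:
    """Empirical fallback threshold for (quasi-)separated data.

    Bins the observed MAM in ``bin_mm`` steps and returns the lowest bin
    centre from which the empirical conditional coverage stays at or
    above ``p_target`` in every populated bin.
    """
    lo = math.floor(x.min() / bin_mm) * bin_mm
    hi = math.ceil(x.max() / bin_mm) * bin_mm
    edges = np.arange(lo, hi + bin_mm, bin_mm)
    which = np.clip(np.digitize(x, edges) - 1, 0, len(edges) - 2)
    n = np.bincount(which, minlength=len(edges) - 1)
    k = np.bincount(which, weights=y, minlength=len(edges) - 1)
    with np.errstate(invalid="ignore"):
        cov = np.where(n > 0, k / np.maximum(n, 1), np.nan)
    ok = np.where(n > 0, cov >= p_target, True)
    # suffix-and: lowest bin from which every populated bin passes
    passing = np.flip(np.logical_and.accumulate(np.flip(ok)))
    idx = np.nonzero(passing)[0]
    if idx.size == 0:
        return float(edges[-1])
    centres = (edges[:-1] + edges[1:]) / 2.0
    return float(centres[idx[0]])


def coverage_prob_at(records: pd.DataFrame, threshold_mm: float = 5.0) -> float:
    """Empirical P(true coverage | observed MAM >= threshold).

    Returns NaN when no record qualifies.
    """
    sel = records["mam_observed_mm"] >= threshold_mm
    if not sel.any():
        return float("nan")
    return float(records.loc[sel, "covered_true"].mean())


def filter_registration(
    records: pd.DataFrame, max_abs_mm: float = 3.0
) -> tuple[pd.DataFrame, int]:
    """Drop records with |registration magnitude| above the cutoff.

    Mirrors the clinical practice of excluding visually inaccurate
    registrations; the number excluded must be disclosed alongside any
    threshold derived from the kept records.
    """
    keep = records["e_mag_mm"].abs() <= max_abs_mm
    return records.loc[keep], int((~keep).sum())


def estimate_a0(
    records: pd.DataFrame,
    p_target: float = 0.99,
    registration_cutoff_mm: float | None = None,
    ridge_penalty: float = 0.0,
) -> A0Estimate:
    """Fit the coverage curve on a record table and solve for A0.

    With ``registration_cutoff_mm`` the fit uses only records whose
    |e_mag| is within the cutoff (the excluded count is reported).
    Complete separation (e.g. the zero-error limit, where the coverage
    curve is a step) falls back to an empirical binned threshold and is
    flagged.
    """
    n_excluded = 0
    if registration_cutoff_mm is not None:
        records, n_excluded = filter_registration(records, registration_cutoff_mm)
    x = records["mam_observed_mm"].to_numpy(dtype=float)
    y = records["covered_true"].to_numpy(dtype=float)
    b0, b1, info = fit_coverage_curve(x, y, ridge_penalty=ridge_penalty)
    fallback = bool(info["separated"])
    if not fallback and b1 <= 0:
        # a decreasing coverage curve means the sweep is degenerate
        fallback = True
    if fallback:
        x_a0 = _binned_threshold(x, y, p_target)
        b0, b1 = float("nan"), float("nan")
        bse = (float("nan"), float("nan"))
    else:
        x_a0 = solve_a0(b0, b1, p_target)
        bse = info["bse"]
    return A0Estimate(
        beta0=b0,
        beta1=b1,
        x_a0_mm=float(x_a0),
        p_coverage_at_5mm=coverage_prob_at(records),
        n_used=len(records),
        n_excluded=n_excluded,
        p_target=p_target,
        separation_fallback=fallback,
        ridge_penalty=ridge_penalty,
        beta_se=bse,
    )
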