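"""Cascade dose-response fitting.

Fits fraction-affected (FA) versus log10 dose with a robust four-parameter
logistic (4PL) model estimated by iteratively reweighted least squares
(Tukey bisquare weights), falling back to a linear-in-log10-dose least
squares fit when the 4PL is non-convergent or degenerate.  Each fit is
summarized by a normalized area under the clipped fitted curve (AUC in
[0, 1]) and, where defined, an IC50.

The 4PL parameterization is::

    FA(x) = bottom + (top - bottom) / (1 + 10**((log10_ac50 - x) * hill))

with x = log10(dose).  AUC integrates ``clip(FA(x), 0, 1)`` over the log10
dose range and divides by the range width, so 0 means inactive and 1 means
complete loss of viability signal at every tested dose.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

from .errors import InsufficientDataError

__all__ = [
    "DoseResponseFit",
    "fourpl",
    "fit_cascade",
    "fit_fourpl",
    "auc",
    "ic50",
    "FOUR_PL",
    "LINEAR",
]

FOUR_PL = "FOUR_PL"
LINEAR = "LINEAR"

#: Tukey bisquare tuning constant (95% Gaussian efficiency).
TUKEY_C = 4.685

_LN10 = math.log(10.0)


def fourpl(x, bottom: float, top: float, log10_ac50: float, hill: float):
    """Evaluate the four-parameter logistic at log10 dose ``x``."""
    x = np.asarray(x, dtype=float)
    u = (np.asarray(x) - log10_ac50) * hill * _LN10
    # logistic via logaddexp for numerical stability at extreme hill slopes
    return bottom + (top - bottom) / (1.0 + np.exp(-u))


@dataclass
class DoseResponseFit:
    """One fitted drug-model dose-response record."""

    drug_id: Optional[str]
    model_id: Optional[str]
    fit_kind: str  # FOUR_PL or LINEAR
    params: dict
    converged: bool
    rmse: float
    auc: float
    ic50_uM: Optional[float]
    ic50_flag: str = "ok"  # "ok" | "no crossing"
    dose_range_uM: tuple = (None, None)
    n_points: int = 0
    fallback_reason: Optional[str] = None
    weights: Optional[np.ndarray] = field(default=None, repr=False)

    def predict(self, log10_dose):
        """Fitted FA at log10 dose (unclipped)."""
        x = np.asarray(log10_dose, dtype=float)
        if self.fit_kind == FOUR_PL:
            p = self.params
            return fourpl(x, p["bottom"], p["top"], p["log10_ac50"], p["hill"])
        return self.params["intercept"] + self.params["slope"] * x


# ---------------------------------------------------------------------------
# analytic integration of the clipped curve
# ---------------------------------------------------------------------------

def _fourpl_antideriv(x: float, bottom: float, top: float,
                      log10_ac50: float, hill: float) -> float:
    # d/dx [ (top-bottom)/(hill ln10) * log(1+e^u) ] = (top-bottom) * sigmoid(u)
    u = (x - log10_ac50) * hill * _LN10
    return bottom * x + (top - bottom) / (hill * _LN10) * np.logaddexp(0.0, u)


def _fourpl_solve(level: float, bottom: float, top: float,
                  log10_ac50: float, hill: float) -> Optional[float]:
    """log10 dose where the 4PL equals ``level``; None if never."""
    lo, hi = min(bottom, top), max(bottom, top)
    if not (lo < level < hi):
        return None
    ratio = (top - bottom) / (level - bottom) - 1.0
    if ratio <= 0:
        return None
    return log10_ac50 - math.log10(ratio) / hill


def _clipped_fourpl_integral(x0: float, x1: float, bottom: float, top: float,
                             log10_ac50: float, hill: float) -> float:
    """Exact integral of clip(4PL, 0, 1) over [x0, x1]."""
    breaks = [x0, x1]
    for level in (0.0, 1.0):
        xc = _fourpl_solve(level, bottom, top, log10_ac50, hill)
        if xc is not None and x0 < xc < x1:
            breaks.append(xc)
    breaks = sorted(breaks)
    total = 0.0
    for a, b in zip(breaks[:-1], breaks[1:]):
        mid = fourpl(0.5 * (a + b), bottom, top, log10_ac50, hill)
        if mid <= 0.0:
            continue
        if mid >= 1.0:
            total += b - a
        else:
            total += (_fourpl_antideriv(b, bottom, top, log10_ac50, hill)
                      - _fourpl_antideriv(a, bottom, top, log10_ac50, hill))
    return total


def _clipped_linear_integral(x0: float, x1: float,
                             intercept: float, slope: float) -> float:
    breaks = [x0, x1]
    if slope != 0.0:
        for level in (0.0, 1.0):
            xc = (level - intercept) / slope
            if x0 < xc < x1:
                breaks.append(xc)
    breaks = sorted(breaks)
    total = 0.0
    for a, b in zip(breaks[:-1], breaks[1:]):
        ga = min(max(intercept + slope * a, 0.0), 1.0)
        gb = min(max(intercept + slope * b, 0.0), 1.0)
        total += 0.5 * (ga + gb) * (b - a)
    return total


def fourpl_auc(bottom: float, top: float, log10_ac50: float, hill: float,
               dose_range_uM: Sequence[float]) -> float:
    """Normalized clipped AUC of a 4PL given directly by its parameters."""
    x0, x1 = (math.log10(float(d)) for d in dose_range_uM)
    if not x0 < x1:
        raise ValueError("dose range must satisfy min < max")
    return _clipped_fourpl_integral(x0, x1, bottom, top,
                                    log10_ac50, hill) / (x1 - x0)


def auc(fit: DoseResponseFit, dose_range_uM: Sequence[float]) -> float:
    """Normalized area under the clipped fitted curve over a dose range.

    Integrates ``clip(FA_hat, 0, 1)`` over log10 dose and divides by the
    log10 range width, so the result lies in [0, 1].
    """
    dmin, dmax = float(dose_range_uM[0]), float(dose_range_uM[1])
    if not (0 < dmin < dmax):
        raise ValueError(f"invalid dose range [{dmin}, {dmax}]")
    x0, x1 = math.log10(dmin), math.log10(dmax)
    if fit.fit_kind == FOUR_PL:
        p = fit.params
        area = _clipped_fourpl_integral(x0, x1, p["bottom"], p["top"],
                                        p["log10_ac50"], p["hill"])
    else:
        area = _clipped_linear_integral(x0, x1, fit.params["intercept"],
                                        fit.params["slope"])
    return area / (x1 - x0)


def ic50(fit: DoseResponseFit,
         dose_range_uM: Optional[Sequence[float]] = None):
    """Dose (µM) where the fitted curve crosses FA = 0.5 within range.

    Returns ``(dose or None, flag)``; flag is ``"no crossing"`` when the
    curve never reaches 0.5 inside the tested range.
    """
    if dose_range_uM is None:
        dose_range_uM = fit.dose_range_uM
    x0, x1 = math.log10(dose_range_uM[0]), math.log10(dose_range_uM[1])
    if fit.fit_kind == FOUR_PL:
        p = fit.params
        xc = _fourpl_solve(0.5, p["bottom"], p["top"],
                           p["log10_ac50"], p["hill"])
    else:
        slope = fit.params["slope"]
        xc = ((0.5 - fit.params["intercept"]) / slope) if slope != 0 else None
    if xc is None or not (x0 - 1e-12 <= xc <= x1 + 1e-12):
        return None, "no crossing"
    return 10.0 ** xc, "ok"


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _default_bounds(x: np.ndarray):
    lo = (-0.5, -0.5, float(np.min(x)) - 1.0, 0.1)
    hi = (0.5, 1.5, float(np.max(x)) + 1.0, 10.0)
    return np.array(lo), np.array(hi)


def _init_params(x: np.ndarray, y: np.ndarray, lb: np.ndarray,
                 ub: np.ndarray) -> np.ndarray:
    doses = np.unique(x)
    means = np.array([y[x == d].mean() for d in doses])
    p0 = np.array([
        float(means.min()),
        float(means.max()),
        float(np.median(doses)),
        1.0,
    ])
    return np.clip(p0, lb, ub)


def _mad_scale(r: np.ndarray) -> float:
    s = 1.4826 * np.median(np.abs(r - np.median(r)))
    if s <= 0:
        s = float(np.std(r))
    return s


def fit_fourpl(x: np.ndarray, y: np.ndarray, *, robust: bool = True,
               max_iter: int = 50, bounds=None):
    """4PL fit by (optionally robust) least squares.

    Returns ``(params, converged, jac_rank, weights)``.  With
    ``robust=True`` this is IRLS with Tukey bisquare weights recomputed
    from MAD-scaled residuals each round; convergence is declared when the
    parameter vector stabilizes (or residuals vanish).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if bounds is None:
        lb, ub = _default_bounds(x)
    else:
        lb, ub = (np.asarray(b, float) for b in bounds)
    p = _init_params(x, y, lb, ub)
    w = np.ones_like(y)
    converged = False
    result = None
    scale = None  # fixed after the first round: re-estimating from few
    # points makes the bisquare weights oscillate without converging
    n_rounds = max_iter if robust else 1
    for i in range(n_rounds):
        sw = np.sqrt(w)

        def resid(params, _sw=sw):
            return _sw * (fourpl(x, *params) - y)

        def jac(params, _sw=sw):
            bottom, top, a, h = params
            u = (x - a) * h * _LN10
            s = 1.0 / (1.0 + np.exp(-u))
            ds = (top - bottom) * s * (1.0 - s)
            cols = np.stack([1.0 - s, s, -ds * h * _LN10,
                             ds * (x - a) * _LN10], axis=1)
            return _sw[:, None] * cols

        result = least_squares(resid, p, jac=jac, bounds=(lb, ub),
                               method="trf", xtol=1e-10, ftol=1e-10,
                               gtol=1e-10, max_nfev=200)
        p_new = result.x
        if not robust:
            p, converged = p_new, bool(result.success)
            break
        r = fourpl(x, *p_new) - y
        if scale is None:
            scale = _mad_scale(r)
        if scale < 1e-12:  # (near-)exact fit: nothing left to reweight
            p, converged = p_new, True
            break
        u = r / (TUKEY_C * scale)
        w_new = np.where(np.abs(u) < 1.0, (1.0 - u ** 2) ** 2, 0.0)
        if w_new.sum() < 3:  # pathological: refuse to discard everything
            w_new = np.ones_like(y)
        params_stable = np.all(np.abs(p_new - p) <= 1e-6 * (1.0 + np.abs(p)))
        weights_stable = np.max(np.abs(w_new - w)) < 1e-4
        if i > 0 and (params_stable or weights_stable):
            p, converged = p_new, True
            break
        p, w = p_new, w_new
    jac_rank = _effective_rank(x, p)
    if not np.all(np.isfinite(p)):
        converged = False
    return p, converged, jac_rank, w


def _effective_rank(x: np.ndarray, params: np.ndarray,
                    rel_tol: float = 1e-2) -> int:
    """Practical rank of the 4PL Jacobian over the distinct doses.

    A 3-dose design is structurally rank <= 3 for a 4-parameter model, so
    full rank is never attainable there; the cascade instead requires the
    design-limited rank min(4, n distinct doses).  Singular values below
    ``rel_tol`` of the largest count as zero, which is what routes flat or
    shallow curves (whose AC50/Hill columns vanish) to the linear branch.
    """
    bottom, top, a, h = params
    xd = np.unique(x)
    u = (xd - a) * h * _LN10
    s = 1.0 / (1.0 + np.exp(-u))
    ds = (top - bottom) * s * (1.0 - s)
    jac = np.stack([1.0 - s, s, -ds * h * _LN10, ds * (xd - a) * _LN10],
                   axis=1)
    sv = np.linalg.svd(jac, compute_uv=False)
    return int(np.sum(sv > rel_tol * sv[0])) if sv[0] > 0 else 0


def _fit_linear(x: np.ndarray, y: np.ndarray):
    slope, intercept = np.polyfit(x, y, 1)
    return float(intercept), float(slope)


def _canonicalize(params: np.ndarray) -> dict:
    bottom, top, log10_ac50, hill = (float(v) for v in params)
    if top < bottom:  # decreasing curve: represent with bottom <= top
        bottom, top, hill = top, bottom, -hill
    return {"bottom": bottom, "top": top,
            "log10_ac50": log10_ac50, "hill": hill}


def fit_cascade(log10_doses, fa, *, drug_id: Optional[str] = None,
                model_id: Optional[str] = None, dose_range_uM=None,
                max_iter: int = 50) -> DoseResponseFit:
    """Fit the cascade model to (log10 dose, FA) observations.

    Attempts a robust 4PL fit first; falls back to a linear fit in log10
    dose when IRLS does not converge, the Jacobian is rank-deficient, or
    the Hill slope sits on a bound without beating the linear fit's RMSE.
    """
    x = np.asarray(log10_doses, dtype=float).ravel()
    y = np.asarray(fa, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("log10_doses and fa must have equal length")
    n_doses = np.unique(x).size
    if n_doses < 3:
        raise InsufficientDataError(
            f"need >= 3 distinct doses, got {n_doses}")
    if dose_range_uM is None:
        dose_range_uM = (10.0 ** x.min(), 10.0 ** x.max())

    lb, ub = _default_bounds(x)
    intercept, slope = _fit_linear(x, y)
    rmse_lin = float(np.sqrt(np.mean((intercept + slope * x - y) ** 2)))

    fallback = None
    weights = None
    try:
        # <= 4 points cannot support outlier down-weighting on a 4-parameter
        # model; a single weighted solve suffices before the rank check
        p, converged, jac_rank, weights = fit_fourpl(
            x, y, robust=x.size > 4, max_iter=max_iter, bounds=(lb, ub))
        pred = fourpl(x, *p)
        rmse_4pl = float(np.sqrt(np.mean((pred - y) ** 2)))
        if not converged:
            fallback = "irls did not converge"
        elif jac_rank < min(4, n_doses):
            fallback = "rank-deficient jacobian"
        else:
            hill = p[3]
            at_bound = (abs(hill - lb[3]) < 1e-6) or (abs(hill - ub[3]) < 1e-6)
            if at_bound and rmse_4pl >= rmse_lin - 1e-12:
                fallback = "hill at bound without RMSE gain over linear"
    except Exception as exc:  # optimizer blow-up counts as non-convergence
        fallback = f"optimizer failure: {exc}"

    if fallback is None:
        fit = DoseResponseFit(
            drug_id=drug_id, model_id=model_id, fit_kind=FOUR_PL,
            params=_canonicalize(p), converged=True, rmse=rmse_4pl,
            auc=float("nan"), ic50_uM=None,
            dose_range_uM=tuple(dose_range_uM), n_points=x.size,
            weights=weights)
    else:
        fit = DoseResponseFit(
            drug_id=drug_id, model_id=model_id, fit_kind=LINEAR,
            params={"intercept": intercept, "slope": slope},
            converged=True, rmse=rmse_lin, auc=float("nan"), ic50_uM=None,
            dose_range_uM=tuple(dose_range_uM), n_points=x.size,
            fallback_reason=fallback)

    fit.auc = auc(fit, dose_range_uM)
    fit.ic50_uM, fit.ic50_flag = ic50(fit, dose_range_uM)
    return fit


def fit_screen(normalized, dose_range_uM=None, max_iter: int = 50):
    """Cascade-fit every (model, drug) group of a normalized long table.

    ``normalized`` needs columns model, drug_id, dose_uM, FA (replicates
    pooled).  Returns a list of :class:`DoseResponseFit`.
    """
    import pandas as pd  # noqa: F401  (kept light; caller passes a frame)

    fits = []
    for (model, drug), grp in normalized.groupby(["model", "drug_id"],
                                                 sort=True):
        x = np.log10(grp["dose_uM"].to_numpy(float))
        fits.append(fit_cascade(x, grp["FA"].to_numpy(float),
                                drug_id=drug, model_id=model,
                                dose_range_uM=dose_range_uM,
                                max_iter=max_iter))
    return fits


def fits_to_frame(fits):
    """Flatten fit records into a tidy frame (one row per drug-model)."""
    import pandas as pd

    rows = []
    for f in fits:
        row = {"drug_id": f.drug_id, "model_id": f.model_id,
               "fit_kind": f.fit_kind, "converged": f.converged,
               "rmse": f.rmse, "auc": f.auc, "ic50_uM": f.ic50_uM,
               "ic50_flag": f.ic50_flag,
               "fallback_reason": f.fallback_reason}
        for k, v in f.params.items():
            row[f"param_{k}"] = v
        rows.append(row)
    return pd.DataFrame(rows)
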