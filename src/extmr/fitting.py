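"""Coefficient estimation for the Extended Mooney-Rivlin model.

Two routes exist, mirroring the admissibility problem of the direct fit:

* **direct_cubic** — ordinary least-squares cubic of sigma_Ext on eps; the
  four polynomial coefficients map affinely (and invertibly) onto
  (B, C1, C2, H). Valid only when the strain-free term a0 = B(lam_C - 1) is
  positive, because B is an elastic-modulus scale and must stay positive.
* **window_B_plus_D** — when the full-range fit returns a non-positive
  intercept (the best mathematical fit can be physically inadmissible), B is
  instead read off a regression restricted to the initial portion of the
  curve (default eps <= 0.5), where the intercept is positive. With B fixed,
  the auxiliary statistic

      D = (sigma_Ext - B(lam_C - 1)) / eps
        = [C2 + C1 + H - B] + eps [C1 + 2H] + eps^2 [H]

  is a quadratic in strain, and a second-order least-squares fit of D
  recovers C1, C2 and H.

All regressions are closed-form, unweighted least squares; there is no
random initialisation anywhere, so fits are deterministic.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .constitutive import (
    LAMBDA_C_DEFAULT,
    ExtMRCoefficients,
    StressStrainCurve,
    model_sigma_ext_strain,
    model_true_stress,
)
from .errors import (
    DegenerateVarianceError,
    InsufficientDataError,
    NonpositiveInterceptError,
    RankDeficiencyError,
)

__all__ = [
    "CubicFit",
    "DSample",
    "FitRoute",
    "ExtMRFit",
    "fit_cubic",
    "map_cubic",
    "estimate_B_window",
    "compute_D",
    "fit_D_quadratic",
    "fit_pipeline",
    "r_squared",
]

log = logging.getLogger(__name__)


class FitRoute(str, enum.Enum):
    DIRECT_CUBIC = "direct_cubic"
    WINDOW_B_PLUS_D = "window_B_plus_D"


@dataclass(frozen=True)
class CubicFit:
    """Raw third-order polynomial regression of sigma_Ext on eps."""

    a0: float
    a1: float
    a2: float
    a3: float
    r_squared: float
    n_points: int

    @property
    def coef(self) -> np.ndarray:
        return np.array([self.a0, self.a1, self.a2, self.a3])


@dataclass(frozen=True)
class DSample:
    """One value of the fixed-B auxiliary statistic D at strain eps."""

    eps: float
    d_value: float


@dataclass(frozen=True)
class ExtMRFit:
    """A completed fit: coefficients, route provenance and diagnostics.

    ``r_squared`` is always evaluated on the Extended Mooney stress scale
    against the final model, so the two routes are directly comparable;
    the route's own regression R^2 (e.g. of the D-quadratic) lives in
    ``diagnostics``.
    """

    coefficients: ExtMRCoefficients
    route: FitRoute
    r_squared: float
    window_eps_max: Optional[float] = None
    diagnostics: dict = field(default_factory=dict)


def _polyfit(eps: np.ndarray, y: np.ndarray, deg: int) -> np.ndarray:
    """Least-squares polynomial fit, ascending coefficients."""
    vand = np.vander(eps, deg + 1, increasing=True)
    if np.linalg.matrix_rank(vand) < deg + 1:
        raise RankDeficiencyError(
            f"degenerate strain grid: cannot fit degree-{deg} polynomial")
    coef, *_ = np.linalg.lstsq(vand, y, rcond=None)
    return coef


def r_squared(observed, predicted) -> float:
    """Coefficient of determination 1 - SS_res / SS_tot."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1:
        raise ValueError("observed and predicted must be 1-D and equal length")
    if obs.size < 2:
        raise InsufficientDataError("R^2 needs at least two observations")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0.0:
        raise DegenerateVarianceError(
            "all observed values identical; R^2 undefined")
    ss_res = float(np.sum((obs - pred) ** 2))
    return 1.0 - ss_res / ss_tot


def fit_cubic(curve: StressStrainCurve) -> CubicFit:
    """Ordinary least-squares cubic of sigma_Ext on eps."""
    if len(curve) < 4:
        raise InsufficientDataError(
            f"cubic regression needs >= 4 samples, got {len(curve)}")
    coef = _polyfit(curve.eps, curve.sigma_ext, 3)
    pred = np.polynomial.polynomial.polyval(curve.eps, coef)
    try:
        r2 = r_squared(curve.sigma_ext, pred)
    except DegenerateVarianceError:
        r2 = 1.0  # constant observed data fitted exactly by its own constant
    return CubicFit(*map(float, coef), r_squared=r2, n_points=len(curve))


def map_cubic(fit: CubicFit,
              lam_c: float = LAMBDA_C_DEFAULT) -> Optional[ExtMRCoefficients]:
    """Map raw cubic coefficients onto (B, C1, C2, H).

    Inverts the bracket structure of the strain-form cubic:
    B = a0/(lam_C - 1), H = a3, C1 = a2 - 2H, C2 = a1 - C1 - H + B.

    Returns ``None`` (the inadmissible flag) when a0 <= 0: a non-positive
    strain-free term would force B <= 0, which is physically inadmissible
    however well it minimises the residuals.
    """
    if fit.a0 <= 0:
        return None
    b = fit.a0 / (lam_c - 1.0)
    h = fit.a3
    c1 = fit.a2 - 2.0 * h
    c2 = fit.a1 - c1 - h + b
    return ExtMRCoefficients(b=b, c1=c1, c2=c2, h=h, lam_c=lam_c)


def estimate_B_window(curve: StressStrainCurve, eps_max: float = 0.5,
                      lam_c: float = LAMBDA_C_DEFAULT) -> float:
    """Estimate B from the initial portion of the curve (eps <= eps_max).

    A polynomial regression restricted to the window is extrapolated to
    eps = 0; the intercept there equals B(lam_C - 1). Cubic order is kept
    when the window holds >= 4 points, degrading to quadratic (>= 3) or
    linear (>= 2) with a logged downgrade. A higher-order extrapolation to
    eps = 0 is noise-sensitive, so when an order yields a non-positive
    intercept the fit also degrades to the next lower order before giving
    up; only when even the linear intercept is non-positive is the curve
    declared unusable.
    """
    mask = curve.eps <= eps_max
    eps, y = curve.eps[mask], curve.sigma_ext[mask]
    n = eps.size
    if n < 2:
        raise InsufficientDataError(
            f"window eps <= {eps_max} holds only {n} sample(s); "
            "need >= 2 for an intercept estimate")
    deg_max = 3 if n >= 4 else (2 if n == 3 else 1)
    if deg_max < 3:
        log.warning("window fit downgraded to degree %d (%d points)",
                    deg_max, n)
    intercept = None
    for deg in range(deg_max, 0, -1):
        candidate = float(_polyfit(eps, y, deg)[0])
        if candidate > 0:
            if deg < deg_max:
                log.warning(
                    "window fit degree %d gave a non-positive intercept; "
                    "using degree %d", deg_max, deg)
            intercept = candidate
            break
    if intercept is None:
        raise NonpositiveInterceptError(
            "windowed intercept <= 0 at every polynomial order: no positive "
            "B exists for this curve under the model")
    return intercept / (lam_c - 1.0)


def compute_D(curve: StressStrainCurve, b: float,
              lam_c: float = LAMBDA_C_DEFAULT,
              eps_min: Optional[float] = None) -> list[DSample]:
    """The fixed-B statistic D = (sigma_Ext - B(lam_C - 1)) / eps.

    D is 0/0 at eps = 0, so samples below ``eps_min`` (default: the smallest
    strictly positive strain in the curve) are dropped with a logged count.
    """
    if not b > 0:
        raise ValueError(f"B must be positive, got {b}")
    if eps_min is None:
        positive = curve.eps[curve.eps > 0]
        if positive.size == 0:
            raise InsufficientDataError(
                "no strictly positive strains: D is undefined everywhere")
        eps_min = float(positive[0])
    mask = curve.eps >= eps_min
    if not mask.any():
        raise InsufficientDataError(
            f"every sample lies below eps_min = {eps_min}; D undefined")
    n_dropped = int((~mask).sum())
    if n_dropped:
        log.info("compute_D dropped %d sample(s) below eps_min = %g",
                 n_dropped, eps_min)
    eps = curve.eps[mask]
    d = (curve.sigma_ext[mask] - b * (lam_c - 1.0)) / eps
    return [DSample(float(e), float(v)) for e, v in zip(eps, d)]


def fit_D_quadratic(d_samples: Sequence[DSample], b: float,
                    lam_c: float = LAMBDA_C_DEFAULT,
                    window_eps_max: Optional[float] = None) -> ExtMRFit:
    """Second-order least-squares fit of D on eps with B held fixed.

    The quadratic coefficients (d0, d1, d2) map onto the remaining model
    parameters: H = d2, C1 = d1 - 2H, C2 = d0 - C1 - H + B.
    """
    if len(d_samples) < 3:
        raise InsufficientDataError(
            f"D-quadratic needs >= 3 samples, got {len(d_samples)}")
    eps = np.array([s.eps for s in d_samples])
    d = np.array([s.d_value for s in d_samples])
    if np.unique(eps).size < 3:
        raise InsufficientDataError("D-quadratic needs >= 3 distinct strains")
    d0, d1, d2 = map(float, _polyfit(eps, d, 2))
    h = d2
    c1 = d1 - 2.0 * h
    c2 = d0 - c1 - h + b
    coeffs = ExtMRCoefficients(b=b, c1=c1, c2=c2, h=h, lam_c=lam_c)
    pred = d0 + eps * (d1 + eps * d2)
    try:
        d_r2 = r_squared(d, pred)
    except DegenerateVarianceError:
        d_r2 = 1.0
    return ExtMRFit(coefficients=coeffs, route=FitRoute.WINDOW_B_PLUS_D,
                    r_squared=d_r2, window_eps_max=window_eps_max,
                    diagnostics={"d_regression_r_squared": d_r2})


def _diagnostics(curve: StressStrainCurve,
                 coeffs: ExtMRCoefficients) -> tuple[float, dict]:
    pred_ext = model_sigma_ext_strain(coeffs, curve.eps)
    res = curve.sigma_ext - pred_ext
    r2_ext = r_squared(curve.sigma_ext, pred_ext)
    diag = {
        "rmse_ext": float(np.sqrt(np.mean(res**2))),
        "max_abs_residual_ext": float(np.max(np.abs(res))),
        "n_points": len(curve),
    }
    # true-stress-scale R^2 logged for transparency; regression is performed
    # on the transformed scale
    try:
        diag["r_squared_true_scale"] = r_squared(
            curve.sigma_true, model_true_stress(coeffs, curve.eps))
    except DegenerateVarianceError:
        diag["r_squared_true_scale"] = 1.0
    return r2_ext, diag


def fit_pipeline(curve: StressStrainCurve, *,
                 lam_c: float = LAMBDA_C_DEFAULT,
                 window_eps_max: float = 0.5,
                 eps_min: Optional[float] = None) -> ExtMRFit:
    """Full fitting workflow for one curve.

    Tries the direct cubic first; when its strain-free term is non-positive
    (inadmissible B), falls back to the windowed-B + fixed-B D-quadratic
    route. Either way the returned fit has B > 0 and an R^2 evaluated on the
    Extended Mooney stress scale against the final model. The route taken,
    lam_C and the window cap are logged on every call.
    """
    cubic = fit_cubic(curve)
    coeffs = map_cubic(cubic, lam_c)
    if coeffs is not None:
        route = FitRoute.DIRECT_CUBIC
        window = None
        extra = {"cubic_regression_r_squared": cubic.r_squared}
    else:
        log.info("direct cubic inadmissible (a0 = %.6g <= 0); switching to "
                 "windowed-B + D route", cubic.a0)
        b = estimate_B_window(curve, eps_max=window_eps_max, lam_c=lam_c)
        d_samples = compute_D(curve, b, lam_c=lam_c, eps_min=eps_min)
        d_fit = fit_D_quadratic(d_samples, b, lam_c=lam_c,
                                window_eps_max=window_eps_max)
        coeffs = d_fit.coefficients
        route = FitRoute.WINDOW_B_PLUS_D
        window = window_eps_max
        extra = dict(d_fit.diagnostics)
    r2, diag = _diagnostics(curve, coeffs)
    diag.update(extra)
    log.info("fit %s: route=%s lam_c=%g window_eps_max=%g R2=%.6f",
             curve.site_label or "<unnamed>", route.value, lam_c,
             window_eps_max, r2)
    return ExtMRFit(coefficients=coeffs, route=route, r_squared=r2,
                    window_eps_max=window, diagnostics=diag)
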