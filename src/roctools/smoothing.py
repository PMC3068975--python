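"""Smoothed ROC curves: binormal regression, kernel density, parametric fits.

Binormal smoothing assumes some monotone transform makes both class
distributions normal, in which case probit(se) is linear in probit(1 - sp):

    probit(se) = a + b * probit(1 - sp)

``a`` and ``b`` are estimated by ordinary least squares over the observed
interior curve points (not by maximum likelihood), after removing the
infinite-probit endpoints and deduplicating plateau points.  The smoothed
curve is evaluated on a uniform specificity grid; its total area has the
closed form Phi(a / sqrt(1 + b^2)), which the trapezoidal grid area matches
to quadrature accuracy.

The density and distribution-fit smoothers instead estimate the two class
densities (Gaussian kernel with Silverman's bandwidth, or a maximum-
likelihood parametric fit) and rebuild the curve from the class cumulative
distributions over a dense cut-off grid.  User-supplied densities on a
shared grid are accepted as well.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats

from .curve import AUCValue, PartialRange, ROCCurve, _area_arrays, _interp_conjugate
from .errors import FitError, InvalidInputError

__all__ = [
    "SmoothROCCurve",
    "fit_binormal",
    "binormal_curve",
    "binormal_smooth",
    "density_smooth",
    "distribution_fit_smooth",
    "smooth_from_densities",
    "smooth_samples",
    "smooth",
]


@dataclass(frozen=True, eq=False)
class SmoothROCCurve:
    """A smoothed ROC curve on a dense (sp, se) traversal.

    ``sp_grid`` is non-decreasing with matching ``se_values``; ``params``
    records the fitted parameters of the smoothing method; ``source`` keeps
    the originating empirical curve when there is one, so bootstrap
    procedures can re-smooth resampled data with the same settings.
    """

    method: str
    sp_grid: np.ndarray
    se_values: np.ndarray
    params: dict
    source: Optional[ROCCurve] = None

    def auc(self) -> AUCValue:
        return AUCValue(float(np.trapezoid(self.se_values, self.sp_grid)))

    def partial_auc(self, prange: PartialRange) -> AUCValue:
        raw = _area_arrays(self.sp_grid, self.se_values, prange)
        value = AUCValue(raw, partial=prange)
        if prange.standardize:
            from .curve import standardize_pauc

            value = standardize_pauc(value, prange)
        return value

    def se_at_sp(self, sp):
        return _interp_conjugate(self.sp_grid, self.se_values, sp)

    def sp_at_se(self, se):
        return _interp_conjugate(self.se_values[::-1], self.sp_grid[::-1], se)


def fit_binormal(
    specificities: np.ndarray, sensitivities: np.ndarray
) -> tuple[float, float]:
    """OLS fit of probit(se) = a + b * probit(1 - sp) over interior points.

    Points with se or sp at 0 or 1 have infinite probits and are excluded;
    duplicated (sp, se) pairs are collapsed so plateaus are not
    over-weighted.  Returns (a, b).
    """
    sp = np.asarray(specificities, dtype=float)
    se = np.asarray(sensitivities, dtype=float)
    interior = (sp > 0) & (sp < 1) & (se > 0) & (se < 1)
    pts = np.unique(np.column_stack([sp[interior], se[interior]]), axis=0)
    if pts.shape[0] < 3:
        raise FitError(
            "binormal fit needs at least 3 distinct interior curve points"
        )
    x = stats.norm.ppf(1.0 - pts[:, 0])
    y = stats.norm.ppf(pts[:, 1])
    b, a = np.polyfit(x, y, 1)
    return float(a), float(b)


def binormal_curve(
    a: float, b: float, grid_size: int = 512, source: Optional[ROCCurve] = None
) -> SmoothROCCurve:
    """Smoothed curve se(sp) = Phi(a + b * Phi^-1(1 - sp)) on a uniform grid."""
    sp = np.linspace(0.0, 1.0, grid_size)
    with np.errstate(divide="ignore"):
        se = stats.norm.cdf(a + b * stats.norm.ppf(1.0 - sp))
    se[0], se[-1] = 1.0, 0.0  # exact endpoints at the infinite probits
    return SmoothROCCurve(
        method="binormal", sp_grid=sp, se_values=se,
        params={"a": a, "b": b}, source=source,
    )


def binormal_smooth(curve: ROCCurve, grid_size: int = 512) -> SmoothROCCurve:
    """Binormal smoothing of an empirical curve (regression, not ML)."""
    a, b = fit_binormal(curve.specificities, curve.sensitivities)
    if b <= 0:
        import warnings

        warnings.warn(
            f"binormal slope b = {b:.4g} <= 0: improper ROC curve", stacklevel=2
        )
    return binormal_curve(a, b, grid_size=grid_size, source=curve)


def _curve_from_cdfs(
    f_case: np.ndarray,
    f_control: np.ndarray,
    method: str,
    params: dict,
    source: Optional[ROCCurve],
) -> SmoothROCCurve:
    """Assemble the (sp, se) traversal from class CDFs over a cut-off grid.

    ``f_case``/``f_control`` are the class CDF values at increasing
    cut-offs (orientation: higher value = more case-like).  se = 1 - F_case
    and sp = F_control; the trivial endpoints are appended explicitly.
    """
    sp = np.concatenate([[0.0], f_control, [1.0]])
    se = np.concatenate([[1.0], 1.0 - f_case, [0.0]])
    # enforce exact monotonicity against floating noise
    sp = np.maximum.accumulate(np.clip(sp, 0.0, 1.0))
    se = np.minimum.accumulate(np.clip(se, 0.0, 1.0))
    return SmoothROCCurve(method=method, sp_grid=sp, se_values=se,
                          params=params, source=source)


def density_smooth(
    curve: ROCCurve,
    bandwidth="silverman",
    grid_size: int = 512,
) -> SmoothROCCurve:
    """Gaussian-kernel density smoothing of the two class distributions.

    ``bandwidth`` is either the name of a rule ("silverman", "scott") or a
    numeric factor multiplying each class's standard deviation.  The
    cut-off grid spans the pooled range extended by 3 bandwidths.
    """
    cases, controls = curve.oriented()
    if np.std(cases) == 0 or np.std(controls) == 0:
        raise FitError(
            "zero variance in a class: use distribution_fit_smooth or the "
            "empirical curve"
        )
    n_distinct = np.unique(np.concatenate([cases, controls])).size
    if n_distinct <= 10:
        import warnings

        warnings.warn(
            f"only {n_distinct} distinct marker values; kernel smoothing "
            "assumes a continuous marker", stacklevel=2,
        )
    if isinstance(bandwidth, str):
        kde_case = stats.gaussian_kde(cases, bw_method=bandwidth)
        kde_ctrl = stats.gaussian_kde(controls, bw_method=bandwidth)
    else:
        kde_case = stats.gaussian_kde(cases, bw_method=bandwidth / np.std(cases, ddof=1))
        kde_ctrl = stats.gaussian_kde(controls, bw_method=bandwidth / np.std(controls, ddof=1))
    h_case = float(np.sqrt(kde_case.covariance[0, 0]))
    h_ctrl = float(np.sqrt(kde_ctrl.covariance[0, 0]))
    pad = 3.0 * max(h_case, h_ctrl)
    lo = min(cases.min(), controls.min()) - pad
    hi = max(cases.max(), controls.max()) + pad
    grid = np.linspace(lo, hi, grid_size)
    dx = grid[1] - grid[0]
    f_case = np.cumsum(kde_case(grid)) * dx
    f_ctrl = np.cumsum(kde_ctrl(grid)) * dx
    f_case = np.clip(f_case / max(f_case[-1], 1e-12), 0.0, 1.0)
    f_ctrl = np.clip(f_ctrl / max(f_ctrl[-1], 1e-12), 0.0, 1.0)
    return _curve_from_cdfs(
        f_case, f_ctrl, "density",
        {"bandwidth_case": h_case, "bandwidth_control": h_ctrl},
        curve,
    )


_FAMILIES = {
    "normal": (stats.norm, {}, lambda x: True),
    "lognormal": (stats.lognorm, {"floc": 0}, lambda x: np.all(x > 0)),
    "exponential": (stats.expon, {"floc": 0}, lambda x: np.all(x >= 0)),
    "gamma": (stats.gamma, {"floc": 0}, lambda x: np.all(x > 0)),
    "logistic": (stats.logistic, {}, lambda x: True),
}


def distribution_fit_smooth(
    curve: ROCCurve, family: str = "normal", grid_size: int = 512
) -> SmoothROCCurve:
    """Parametric smoothing: maximum-likelihood fit of a family per class."""
    if family not in _FAMILIES:
        raise InvalidInputError(
            f"unknown family {family!r}; choose from {sorted(_FAMILIES)}"
        )
    dist, fit_kwargs, support_ok = _FAMILIES[family]
    cases, controls = curve.oriented()
    if not (support_ok(cases) and support_ok(controls)):
        raise FitError(f"data outside the support of the {family} family")
    try:
        par_case = dist.fit(cases, **fit_kwargs)
        par_ctrl = dist.fit(controls, **fit_kwargs)
    except Exception as exc:  # scipy raises assorted fit failures
        raise FitError(f"{family} fit failed: {exc}") from exc
    lo = min(dist.ppf(1e-6, *par_case), dist.ppf(1e-6, *par_ctrl))
    hi = max(dist.ppf(1 - 1e-6, *par_case), dist.ppf(1 - 1e-6, *par_ctrl))
    grid = np.linspace(lo, hi, grid_size)
    return _curve_from_cdfs(
        dist.cdf(grid, *par_case),
        dist.cdf(grid, *par_ctrl),
        "distribution_fit",
        {"family": family, "case": tuple(map(float, par_case)),
         "control": tuple(map(float, par_ctrl))},
        curve,
    )


def smooth_from_densities(
    case_density, control_density, grid, source: Optional[ROCCurve] = None
) -> SmoothROCCurve:
    """Build a smoothed curve from user-supplied class densities.

    Densities must be non-negative, tabulated on the same increasing grid,
    and integrate to approximately 1 (renormalised with a warning beyond a
    1e-3 tolerance).
    """
    fc = np.asarray(case_density, dtype=float)
    fn = np.asarray(control_density, dtype=float)
    g = np.asarray(grid, dtype=float)
    if fc.shape != g.shape or fn.shape != g.shape:
        raise InvalidInputError("densities and grid must share one shape")
    if np.any(fc < 0) or np.any(fn < 0):
        raise InvalidInputError("densities must be non-negative")
    if np.any(np.diff(g) <= 0):
        raise InvalidInputError("grid must be strictly increasing")
    import warnings

    cdf_c = np.concatenate([[0.0], np.cumsum(0.5 * (fc[1:] + fc[:-1]) * np.diff(g))])
    cdf_n = np.concatenate([[0.0], np.cumsum(0.5 * (fn[1:] + fn[:-1]) * np.diff(g))])
    for name, cdf in (("case", cdf_c), ("control", cdf_n)):
        if abs(cdf[-1] - 1.0) > 1e-3:
            warnings.warn(
                f"{name} density integrates to {cdf[-1]:.4g}; renormalising",
                stacklevel=2,
            )
    cdf_c /= cdf_c[-1]
    cdf_n /= cdf_n[-1]
    return _curve_from_cdfs(cdf_c, cdf_n, "custom", {}, source)


def smooth_samples(
    cases: np.ndarray,
    controls: np.ndarray,
    direction: str,
    method: str = "binormal",
    **options,
) -> SmoothROCCurve:
    """Smooth raw samples directly (bootstrap replicates use this path)."""
    from .curve import roc_from_samples

    curve = roc_from_samples(cases, controls, direction=direction)
    return smooth(curve, method=method, **options)


def smooth(curve: ROCCurve, method: str = "binormal", **options) -> SmoothROCCurve:
    """Dispatch to a smoothing method by name."""
    if method == "binormal":
        return binormal_smooth(curve, **options)
    if method == "density":
        return density_smooth(curve, **options)
    if method == "distribution_fit":
        return distribution_fit_smooth(curve, **options)
    raise InvalidInputError(f"unknown smoothing method {method!r}")
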