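"""Confidence intervals for AUC, partial AUC, thresholds and curve shapes.

The AUC interval uses DeLong's asymptotic variance built from placement
values.  Everything else is bootstrap: subjects are resampled (stratified
by default), the curve is rebuilt, the statistic of interest recomputed,
and equal-tailed percentile bounds taken over the replicates.  Threshold
intervals are rectangular — per-coordinate percentile bounds of the
(specificity, sensitivity) reached by the *fixed* cut-off on each replicate
— and are always reported jointly, never one coordinate alone.  CI shapes
evaluate the interpolated conjugate coordinate over a grid of fixed levels
and join the per-point bounds into a band.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .curve import (
    PartialRange,
    ROCCurve,
    _area_arrays,
    _curve_points,
    _interp_conjugate,
)
from .compare import delong_placements, _mw_auc
from .errors import EstimationError, InvalidInputError
from .resampling import ResamplePlan, percentile_interval, resample_index_pairs
from .smoothing import SmoothROCCurve, smooth_samples

__all__ = [
    "IntervalEstimate",
    "ThresholdCI",
    "ci_auc_delong",
    "ci_bootstrap_metric",
    "ci_threshold",
    "ci_shape",
    "DEFAULT_SHAPE_GRID",
]

DEFAULT_SHAPE_GRID = np.round(np.arange(0.0, 1.0001, 0.05), 10)


@dataclass(frozen=True)
class IntervalEstimate:
    """A point estimate with confidence bounds, or a banded shape.

    For scalar quantities ``estimate``/``lower``/``upper`` are floats and
    ``grid`` is None.  For shapes, ``grid`` holds the fixed coordinates and
    the three arrays the per-point band.
    """

    estimate: Union[float, np.ndarray]
    lower: Union[float, np.ndarray]
    upper: Union[float, np.ndarray]
    level: float
    method: str
    grid: Optional[np.ndarray] = None
    degenerate: bool = False

    def to_frame(self) -> pd.DataFrame:
        """Shape band as a 4-column table (coordinate, lower, estimate, upper)."""
        if self.grid is None:
            raise InvalidInputError("not a shape interval")
        return pd.DataFrame(
            {
                "coordinate": self.grid,
                "lower": self.lower,
                "estimate": self.estimate,
                "upper": self.upper,
            }
        )


@dataclass(frozen=True)
class ThresholdCI:
    """Rectangular bootstrap CI of the operating point at a fixed cut-off."""

    threshold: float
    specificity: tuple[float, float, float]  # (lower, estimate, upper)
    sensitivity: tuple[float, float, float]
    level: float

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "specificity": dict(zip(("lower", "estimate", "upper"), self.specificity)),
            "sensitivity": dict(zip(("lower", "estimate", "upper"), self.sensitivity)),
            "level": self.level,
        }


def _check_level(level: float) -> None:
    if not (0.0 < level < 1.0):
        raise InvalidInputError("confidence level must be in (0, 1)")


def ci_auc_delong(curve: ROCCurve, level: float = 0.95) -> IntervalEstimate:
    """DeLong confidence interval for the AUC, truncated to [0, 1]."""
    _check_level(level)
    if curve.n_cases < 2 or curve.n_controls < 2:
        raise EstimationError(
            "DeLong variance needs >= 2 observations per class; "
            "use a bootstrap interval instead"
        )
    pl = delong_placements(curve)
    var = np.var(pl.v10, ddof=1) / curve.n_cases + np.var(pl.v01, ddof=1) / curve.n_controls
    z = stats.norm.ppf(0.5 * (1.0 + level))
    half = z * np.sqrt(var)
    return IntervalEstimate(
        estimate=pl.theta,
        lower=max(0.0, pl.theta - half),
        upper=min(1.0, pl.theta + half),
        level=level,
        method="DeLong",
        degenerate=var == 0.0,
    )


def _replicate_samples(curve: ROCCurve, plan: ResamplePlan, rng):
    for ci, ni in resample_index_pairs(curve.n_cases, curve.n_controls, plan, rng):
        yield curve.cases[ci], curve.controls[ni]


def ci_bootstrap_metric(
    curve: Union[ROCCurve, SmoothROCCurve],
    metric: str = "auc",
    prange: Optional[PartialRange] = None,
    plan: Optional[ResamplePlan] = None,
    level: float = 0.95,
) -> IntervalEstimate:
    """Bootstrap percentile CI for the AUC or partial AUC of a curve.

    Patients are resampled, the curve rebuilt (and re-smoothed when the
    input is a smoothed curve), and the metric recomputed on each
    replicate.
    """
    _check_level(level)
    if plan is None:
        plan = ResamplePlan()
    smoothed = isinstance(curve, SmoothROCCurve)
    if smoothed:
        if curve.source is None:
            raise InvalidInputError(
                "smoothed curve has no source data to resample"
            )
        base = curve.source
        sm_method = curve.method
        if sm_method == "custom":
            raise InvalidInputError("cannot resample a density-only curve")
    else:
        base = curve

    def metric_of(cases, controls):
        if smoothed:
            sm = smooth_samples(cases, controls, base.direction, method=sm_method)
            if metric == "auc":
                return float(sm.auc())
            if metric == "pauc":
                if prange is None:
                    raise InvalidInputError("metric='pauc' requires a range")
                return float(sm.partial_auc(prange))
            raise InvalidInputError(f"unknown metric {metric!r}")
        if metric == "auc":
            if base.direction == "controls_higher":
                return _mw_auc(-cases, -controls)
            return _mw_auc(cases, controls)
        if metric == "pauc":
            if prange is None:
                raise InvalidInputError("metric='pauc' requires a range")
            _, sp, se = _curve_points(cases, controls, base.direction)
            raw = _area_arrays(sp, se, prange)
            if prange.standardize:
                mn, mx = prange.chance_area(), prange.perfect_area()
                return 0.5 * (1.0 + (raw - mn) / (mx - mn))
            return raw
        raise InvalidInputError(f"unknown metric {metric!r}")

    estimate = metric_of(base.cases, base.controls)
    rng = plan.rng()
    reps = np.array(
        [metric_of(c, n) for c, n in _replicate_samples(base, plan, rng)]
    )
    lo, hi = percentile_interval(reps, level)
    label = "smoothed " + metric if smoothed else metric
    return IntervalEstimate(
        estimate=float(estimate), lower=lo, upper=hi, level=level,
        method=f"bootstrap percentile ({label}, {plan.n_replicates} replicates)",
        degenerate=lo == hi,
    )


def ci_threshold(
    curve: ROCCurve,
    threshold: float,
    plan: Optional[ResamplePlan] = None,
    level: float = 0.95,
) -> ThresholdCI:
    """Rectangular bootstrap CI of (specificity, sensitivity) at a cut-off.

    The cut-off stays fixed; each replicate re-evaluates the operating
    point it induces on the resampled data, and the two coordinates get
    independent percentile bounds.
    """
    _check_level(level)
    if plan is None:
        plan = ResamplePlan()
    flip = curve.direction == "controls_higher"
    t = -threshold if flip else threshold

    def point(cases, controls):
        if flip:
            cases, controls = -cases, -controls
        se = float(np.mean(cases >= t))
        sp = float(np.mean(controls < t))
        return sp, se

    sp0, se0 = point(curve.cases, curve.controls)
    rng = plan.rng()
    pts = np.array([point(c, n) for c, n in _replicate_samples(curve, plan, rng)])
    sp_lo, sp_hi = percentile_interval(pts[:, 0], level)
    se_lo, se_hi = percentile_interval(pts[:, 1], level)
    return ThresholdCI(
        threshold=float(threshold),
        specificity=(sp_lo, sp0, sp_hi),
        sensitivity=(se_lo, se0, se_hi),
        level=level,
    )


def ci_shape(
    curve: ROCCurve,
    axis: str = "specificity",
    grid: Optional[Sequence[float]] = None,
    plan: Optional[ResamplePlan] = None,
    level: float = 0.95,
) -> IntervalEstimate:
    """Pointwise percentile CI band of the conjugate coordinate over a grid.

    ``axis="specificity"`` computes the CI of sensitivity at each fixed
    specificity (the default grid steps by 0.05 from 0 to 1), and vice
    versa.  Bounds are joined per point; no simultaneous-band adjustment.
    """
    _check_level(level)
    if axis not in ("specificity", "sensitivity"):
        raise InvalidInputError(f"unknown axis {axis!r}")
    if plan is None:
        plan = ResamplePlan()
    grid = DEFAULT_SHAPE_GRID if grid is None else np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise InvalidInputError("empty grid")
    if np.any((grid < 0) | (grid > 1)):
        raise InvalidInputError("grid values must lie in [0, 1]")

    def conj(cases, controls):
        _, sp, se = _curve_points(cases, controls, curve.direction)
        if axis == "specificity":
            return _interp_conjugate(sp, se, grid)
        return _interp_conjugate(se[::-1], sp[::-1], grid)

    estimate = conj(curve.cases, curve.controls)
    rng = plan.rng()
    reps = np.array([conj(c, n) for c, n in _replicate_samples(curve, plan, rng)])
    alpha = (1.0 - level) / 2.0
    lower = np.quantile(reps, alpha, axis=0, method="linear")
    upper = np.quantile(reps, 1.0 - alpha, axis=0, method="linear")
    conj_name = "sensitivity" if axis == "specificity" else "specificity"
    return IntervalEstimate(
        estimate=np.asarray(estimate),
        lower=lower,
        upper=upper,
        level=level,
        method=f"bootstrap percentile shape ({conj_name} at fixed {axis})",
        grid=grid,
    )
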