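"""Empirical ROC curves: construction, coordinates, AUC and partial AUC.

A ROC curve summarises a numeric marker's ability to separate *cases*
(positive class) from *controls* (negative class).  Thresholds are placed at
the midpoints between consecutive distinct pooled marker values, with -inf
and +inf sentinels, so that every achievable (specificity, sensitivity)
operating point appears exactly once.  Areas are computed with trapezoids;
the total area equals the Mann-Whitney U statistic with ties counted 1/2.

Partial areas can be taken over a sub-interval of either the specificity or
the sensitivity axis, with linear interpolation at the interval bounds, and
optionally standardised with McClish's affine rescaling so that a perfect
curve always scores 1 and a non-discriminant one 0.5 over any region.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Literal, NamedTuple, Optional, Sequence

import numpy as np

from .errors import InvalidInputError

Axis = Literal["specificity", "sensitivity"]
Direction = Literal["auto", "controls_lower", "controls_higher"]

__all__ = [
    "ROCCurve",
    "PartialRange",
    "AUCValue",
    "Coord",
    "build_roc",
    "roc_from_samples",
    "roc_coords",
    "auc",
    "partial_auc",
    "standardize_pauc",
    "best_threshold",
]


@dataclass(frozen=True)
class PartialRange:
    """A sub-interval [lo, hi] of the specificity or sensitivity axis.

    ``standardize`` requests McClish standardisation of partial areas
    computed over this range (chance -> 0.5, perfection -> 1).
    Bounds are fractions in [0, 1] regardless of any display scale.
    """

    lo: float
    hi: float
    axis: Axis = "specificity"
    standardize: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.lo < self.hi <= 1.0):
            raise InvalidInputError(
                f"partial range requires 0 <= lo < hi <= 1, got [{self.lo}, {self.hi}]"
            )
        if self.axis not in ("specificity", "sensitivity"):
            raise InvalidInputError(f"unknown axis {self.axis!r}")

    @property
    def width(self) -> float:
        return self.hi - self.lo

    def perfect_area(self) -> float:
        """Partial area of the perfect ROC curve over this range (= hi - lo)."""
        return self.width

    def chance_area(self) -> float:
        """Partial area of the chance diagonal over this range.

        On the specificity axis the diagonal is se = 1 - sp, so the area is
        the integral of (1 - t) over [lo, hi]; by symmetry the sensitivity
        axis gives the same value.
        """
        return self.width * (1.0 - 0.5 * (self.lo + self.hi))


@dataclass(frozen=True)
class AUCValue:
    """A (partial) area under a ROC curve, always stored as a fraction."""

    value: float
    partial: Optional[PartialRange] = None
    standardized: bool = False

    def __float__(self) -> float:
        return float(self.value)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        if self.partial is None:
            return f"AUCValue({self.value:.6g})"
        tag = "standardized " if self.standardized else ""
        return (
            f"AUCValue({self.value:.6g}, {tag}partial "
            f"{self.partial.axis} [{self.partial.lo}, {self.partial.hi}])"
        )


class Coord(NamedTuple):
    """A single operating point of a ROC curve."""

    threshold: float
    specificity: float
    sensitivity: float
    interpolated: bool = False


@dataclass(frozen=True, eq=False)
class ROCCurve:
    """An empirical ROC curve.

    Arrays are ordered along the curve traversal from (sp=0, se=1) to
    (sp=1, se=0): specificities non-decreasing, sensitivities non-increasing.
    ``thresholds`` holds the cut-off generating each point (with -inf/+inf
    sentinels at the two trivial points).  ``response`` keeps the canonical
    0/1 label vector when the curve was built from a labelled table, which
    lets two curves be recognised as paired.
    """

    cases: np.ndarray
    controls: np.ndarray
    direction: str
    thresholds: np.ndarray
    specificities: np.ndarray
    sensitivities: np.ndarray
    response: Optional[np.ndarray] = None
    scale: str = "fraction"  # presentation hint only; storage is fractions

    @property
    def n_cases(self) -> int:
        return self.cases.size

    @property
    def n_controls(self) -> int:
        return self.controls.size

    def oriented(self) -> tuple[np.ndarray, np.ndarray]:
        """Case/control values transformed so that larger means more case-like."""
        if self.direction == "controls_higher":
            return -self.cases, -self.controls
        return self.cases, self.controls

    def auc(self) -> AUCValue:
        return auc(self)

    def partial_auc(self, prange: PartialRange) -> AUCValue:
        return partial_auc(self, prange)

    def coords(self, at: float, input_axis: str = "threshold") -> Coord:
        return roc_coords(self, at, input_axis)

    def se_at_sp(self, sp) -> np.ndarray | float:
        """Sensitivity at given specificity level(s), linearly interpolated."""
        return _interp_conjugate(self.specificities, self.sensitivities, sp)

    def sp_at_se(self, se) -> np.ndarray | float:
        """Specificity at given sensitivity level(s), linearly interpolated."""
        return _interp_conjugate(
            self.sensitivities[::-1], self.specificities[::-1], se
        )


def _resolve_labels(response: np.ndarray, positive_label) -> np.ndarray:
    """Map an arbitrary two-level response vector onto 0/1 (1 = case)."""
    labels = np.unique(response)
    if labels.size != 2:
        raise InvalidInputError(
            f"response must have exactly 2 distinct labels, found {labels.size}"
        )
    if positive_label is None:
        lset = {str(l) for l in labels}
        if lset == {"0", "1"}:
            positive_label = labels[np.argmax([str(l) == "1" for l in labels])]
        elif lset == {"case", "control"}:
            positive_label = "case"
        else:
            raise InvalidInputError(
                f"cannot infer the positive label from {sorted(lset)}; "
                "pass positive_label explicitly"
            )
    if positive_label not in labels:
        raise InvalidInputError(
            f"positive label {positive_label!r} absent from response"
        )
    return (response == positive_label).astype(np.int8)


def build_roc(
    response: Sequence,
    predictor: Sequence[float],
    positive_label=None,
    direction: Direction = "auto",
) -> ROCCurve:
    """Build an empirical ROC curve from a labelled marker column.

    Parameters
    ----------
    response:
        Two-level class labels; ``{0, 1}`` and ``{"control", "case"}`` are
        recognised automatically, any other pair needs ``positive_label``.
    predictor:
        Numeric marker values, same length as ``response``; must be finite
        (drop incomplete observations before calling).
    direction:
        ``controls_lower`` means controls tend to have lower marker values
        than cases (a higher value votes "case").  ``auto`` picks the
        direction for which the control median does not exceed the case
        median.
    """
    response = np.asarray(response)
    predictor = np.asarray(predictor, dtype=float)
    if response.shape != predictor.shape or response.ndim != 1:
        raise InvalidInputError("response and predictor must be 1-d and same length")
    if not np.all(np.isfinite(predictor)):
        raise InvalidInputError("predictor contains non-finite values")
    y = _resolve_labels(response, positive_label)
    cases = predictor[y == 1]
    controls = predictor[y == 0]
    return roc_from_samples(cases, controls, direction=direction, response=y)


def roc_from_samples(
    cases: Sequence[float],
    controls: Sequence[float],
    direction: Direction = "auto",
    response: Optional[np.ndarray] = None,
) -> ROCCurve:
    """Build an empirical ROC curve from explicit case and control samples."""
    cases = np.asarray(cases, dtype=float)
    controls = np.asarray(controls, dtype=float)
    if cases.size == 0 or controls.size == 0:
        raise InvalidInputError("need at least one case and one control")
    if not (np.all(np.isfinite(cases)) and np.all(np.isfinite(controls))):
        raise InvalidInputError("marker values must be finite")

    if direction == "auto":
        direction = (
            "controls_lower"
            if np.median(controls) <= np.median(cases)
            else "controls_higher"
        )
    elif direction not in ("controls_lower", "controls_higher"):
        raise InvalidInputError(f"unknown direction {direction!r}")

    thresholds, sp, se = _curve_points(cases, controls, direction)
    return ROCCurve(
        cases=cases,
        controls=controls,
        direction=direction,
        thresholds=thresholds,
        specificities=sp,
        sensitivities=se,
        response=None if response is None else np.asarray(response),
    )


def _curve_points(
    cases: np.ndarray, controls: np.ndarray, direction: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Thresholds (midpoints with sentinels) and the (sp, se) traversal."""
    pooled = np.unique(np.concatenate([cases, controls]))
    mids = 0.5 * (pooled[:-1] + pooled[1:])
    thr = np.concatenate([[-np.inf], mids, [np.inf]])

    sc = np.sort(cases)
    sn = np.sort(controls)
    m, n = sc.size, sn.size
    if direction == "controls_lower":
        # positive call: value >= threshold
        se = (m - np.searchsorted(sc, thr, side="left")) / m
        sp = np.searchsorted(sn, thr, side="left") / n
    else:
        # positive call: value <= threshold
        se = np.searchsorted(sc, thr, side="right") / m
        sp = (n - np.searchsorted(sn, thr, side="right")) / n
        # order by increasing specificity for a canonical traversal
        thr, sp, se = thr[::-1], sp[::-1], se[::-1]
    return thr, sp, se


def _interp_conjugate(x: np.ndarray, y: np.ndarray, at) -> np.ndarray | float:
    """Interpolate y at positions ``at`` along a monotone (x, y) traversal.

    ``x`` is non-decreasing (possibly with ties marking vertical segments),
    ``y`` monotone the other way.  Exact hits on an observed x return the
    first point of the tied run, i.e. the most favourable observed y;
    queries between distinct x values are linearly interpolated along the
    unique connecting segment.
    """
    at_arr = np.atleast_1d(np.asarray(at, dtype=float))
    if np.any((at_arr < 0) | (at_arr > 1)):
        raise InvalidInputError("rate-axis coordinates must lie in [0, 1]")
    idx = np.searchsorted(x, at_arr, side="left")
    idx = np.clip(idx, 0, x.size - 1)
    out = np.empty_like(at_arr)
    exact = x[idx] == at_arr
    out[exact] = y[idx[exact]]
    inner = ~exact
    if np.any(inner):
        i1 = idx[inner]
        i0 = i1 - 1
        x0, x1 = x[i0], x[i1]
        frac = (at_arr[inner] - x0) / (x1 - x0)
        out[inner] = y[i0] + frac * (y[i1] - y[i0])
    return out if np.ndim(at) else float(out[0])


def roc_coords(curve: ROCCurve, at: float, input_axis: str = "threshold") -> Coord:
    """Coordinates of the curve point addressed by a threshold or a rate.

    For ``input_axis="threshold"`` the returned point is the operating point
    obtained by actually classifying at that cut-off.  For the rate axes the
    conjugate coordinate is linearly interpolated; the threshold is reported
    only when ``at`` coincides with an observed point, otherwise the result
    is flagged interpolated with a NaN threshold.
    """
    if input_axis == "threshold":
        cases, controls = curve.oriented()
        t = -at if curve.direction == "controls_higher" else at
        se = float(np.mean(cases >= t))
        sp = float(np.mean(controls < t))
        return Coord(float(at), sp, se, interpolated=False)
    if input_axis == "specificity":
        se = curve.se_at_sp(at)
        hit = np.flatnonzero(curve.specificities == at)
        if hit.size:
            i = hit[0]
            return Coord(float(curve.thresholds[i]), float(at), float(se), False)
        return Coord(float("nan"), float(at), float(se), True)
    if input_axis == "sensitivity":
        sp = curve.sp_at_se(at)
        hit = np.flatnonzero(curve.sensitivities == at)
        if hit.size:
            i = hit[-1]
            return Coord(float(curve.thresholds[i]), float(sp), float(at), False)
        return Coord(float("nan"), float(sp), float(at), True)
    raise InvalidInputError(f"unknown input_axis {input_axis!r}")


def _clipped_trapezoid(x: np.ndarray, y: np.ndarray, lo: float, hi: float) -> float:
    """Integral of y dx over x in [lo, hi] along a piecewise-linear traversal.

    Segments are clipped to the window with linear interpolation; vertical
    segments (zero dx) contribute nothing.  ``x`` must be non-decreasing.
    """
    x0, x1 = x[:-1], x[1:]
    y0, y1 = y[:-1], y[1:]
    dx = x1 - x0
    nonvert = dx > 0
    xa = np.clip(x0, lo, hi)
    xb = np.clip(x1, lo, hi)
    w = xb - xa
    keep = nonvert & (w > 0)
    if not np.any(keep):
        return 0.0
    x0k, dxk = x0[keep], dx[keep]
    y0k, y1k = y0[keep], y1[keep]
    fa = (xa[keep] - x0k) / dxk
    fb = (xb[keep] - x0k) / dxk
    ya = y0k + fa * (y1k - y0k)
    yb = y0k + fb * (y1k - y0k)
    return float(np.sum(w[keep] * 0.5 * (ya + yb)))


def _area_arrays(sp: np.ndarray, se: np.ndarray, prange: PartialRange) -> float:
    if prange.axis == "specificity":
        return _clipped_trapezoid(sp, se, prange.lo, prange.hi)
    # sensitivity axis: integrate specificity over the se interval; reverse
    # the traversal so the x coordinate is non-decreasing.
    return _clipped_trapezoid(se[::-1], sp[::-1], prange.lo, prange.hi)


def auc(curve: ROCCurve) -> AUCValue:
    """Total trapezoidal area under the curve (Mann-Whitney with ties 1/2)."""
    value = float(np.trapezoid(curve.sensitivities, curve.specificities))
    return AUCValue(min(max(value, 0.0), 1.0))


def partial_auc(curve: ROCCurve, prange: PartialRange) -> AUCValue:
    """Trapezoidal area restricted to ``prange`` on its axis.

    Interior boundary points are obtained by linear interpolation.  If the
    range requests standardisation the McClish rescaling is applied.
    """
    raw = _area_arrays(curve.specificities, curve.sensitivities, prange)
    result = AUCValue(raw, partial=prange, standardized=False)
    if prange.standardize:
        result = standardize_pauc(result, prange)
    return result


def standardize_pauc(pauc: AUCValue | float, prange: PartialRange) -> AUCValue:
    """McClish standardisation of a partial area.

    Maps the chance diagonal's area over the region to 0.5 and the perfect
    curve's area to 1, linearly:  1/2 (1 + (pAUC - min) / (max - min)).
    """
    raw = float(pauc)
    mn = prange.chance_area()
    mx = prange.perfect_area()
    if mx <= mn:
        raise InvalidInputError(
            "degenerate partial range: perfect and chance areas coincide"
        )
    value = 0.5 * (1.0 + (raw - mn) / (mx - mn))
    return AUCValue(value, partial=prange, standardized=True)


def best_threshold(
    curve: ROCCurve, prange: Optional[PartialRange] = None
) -> Coord:
    """Observed operating point farthest from the chance diagonal.

    Maximises the Youden index se + sp - 1 over observed curve points, over
    the whole curve or restricted to a partial region.  Ties are broken
    toward the higher-specificity point.
    """
    sp = curve.specificities
    se = curve.sensitivities
    if prange is None:
        mask = np.ones(sp.size, dtype=bool)
    else:
        coord = sp if prange.axis == "specificity" else se
        mask = (coord >= prange.lo) & (coord <= prange.hi)
    if not np.any(mask):
        raise InvalidInputError("no observed curve point inside the region")
    youden = se + sp - 1.0
    youden_masked = np.where(mask, youden, -np.inf)
    best = youden_masked == youden_masked.max()
    # tie-break toward higher specificity, then first occurrence
    idx = np.flatnonzero(best)[np.argmax(sp[best])]
    return Coord(float(curve.thresholds[idx]), float(sp[idx]), float(se[idx]))
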