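"""Statistical tests comparing two ROC curves.

Four families of tests are provided:

* DeLong's asymptotic test on AUC differences, built from U-statistic
  placement values and their covariance (paired or unpaired).
* A bootstrap Z-test on the difference of any curve metric (AUC, partial
  AUC, or the AUC of a re-smoothed curve), Z = (theta1 - theta2) / sd(D)
  where D is the replicate-wise metric difference.
* Venkatraman's rank-based permutation tests on the integrated absolute
  difference between the two curves' misclassification profiles (shape
  tests, sensitive to curve differences even at equal AUC).
* A fixed operating-point test: the bootstrap machinery applied to the
  interpolated sensitivity at a given specificity (or vice versa).

All tests emit a :class:`TestResult` serialisable to JSON.  Multiple-testing
corrections are deliberately not applied here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats

from .curve import PartialRange, ROCCurve, _area_arrays, _curve_points, _interp_conjugate
from .errors import EstimationError, InvalidInputError
from .resampling import ResamplePlan, empirical_pvalue, resample_index_pairs

__all__ = [
    "TestResult",
    "PlacementSet",
    "delong_placements",
    "delong_test",
    "bootstrap_test",
    "venkatraman_test",
    "fixed_point_test",
    "are_paired",
]

_ALTERNATIVES = ("two_sided", "greater", "less")


@dataclass(frozen=True)
class TestResult:
    """Outcome of a two-curve comparison test."""

    statistic: float
    p_value: float
    alternative: str
    method: str
    n_resamples: Optional[int] = None
    estimates: Optional[tuple[float, float]] = None
    degenerate: bool = False
    seed: Optional[int] = None

    def format_p(self) -> str:
        if self.p_value == 0.0 and self.n_resamples:
            return f"< {1.0 / self.n_resamples:g}"
        return f"{self.p_value:.4g}"

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "p_display": self.format_p(),
            "alternative": self.alternative,
            "n_resamples": self.n_resamples,
            "estimates": None if self.estimates is None else list(self.estimates),
            "degenerate": self.degenerate,
            "seed": self.seed,
        }


@dataclass(frozen=True)
class PlacementSet:
    """DeLong placement values of a curve.

    ``v10[i]`` is the fraction of controls beaten by case i (ties 1/2),
    ``v01[j]`` the fraction of cases beating control j.  Both means equal
    the trapezoidal AUC exactly.
    """

    v10: np.ndarray
    v01: np.ndarray
    theta: float


def _normal_p(z: float, alternative: str) -> float:
    if alternative == "two_sided":
        return float(2.0 * stats.norm.sf(abs(z)))
    if alternative == "greater":
        return float(stats.norm.sf(z))
    if alternative == "less":
        return float(stats.norm.cdf(z))
    raise InvalidInputError(f"unknown alternative {alternative!r}")


def _mw_auc(cases: np.ndarray, controls: np.ndarray) -> float:
    """Mann-Whitney AUC (ties 1/2) for oriented samples (higher = case-like)."""
    sn = np.sort(controls)
    less = np.searchsorted(sn, cases, side="left").sum()
    leq = np.searchsorted(sn, cases, side="right").sum()
    return (less + 0.5 * (leq - less)) / (cases.size * controls.size)


def delong_placements(curve: ROCCurve) -> PlacementSet:
    """Placement values entering DeLong's variance estimator."""
    cases, controls = curve.oriented()
    m, n = cases.size, controls.size
    sn = np.sort(controls)
    less = np.searchsorted(sn, cases, side="left")
    leq = np.searchsorted(sn, cases, side="right")
    v10 = (less + 0.5 * (leq - less)) / n
    sc = np.sort(cases)
    greater = m - np.searchsorted(sc, controls, side="right")
    geq = m - np.searchsorted(sc, controls, side="left")
    v01 = (greater + 0.5 * (geq - greater)) / m
    theta = float(v10.mean())
    return PlacementSet(v10=v10, v01=v01, theta=theta)


def are_paired(curve1: ROCCurve, curve2: ROCCurve) -> bool:
    """Whether the two curves derive from the same subjects.

    True iff both curves carry a response vector and those vectors are
    identical element-wise (same subjects, same labels, same order).
    """
    r1, r2 = curve1.response, curve2.response
    if r1 is None or r2 is None:
        return False
    return r1.shape == r2.shape and bool(np.all(r1 == r2))


def _check_comparable(curve1: ROCCurve, curve2: ROCCurve, paired: bool) -> None:
    if curve1.direction != curve2.direction:
        raise InvalidInputError(
            "curves were built with opposite directions; rebuild with a "
            "common direction before comparing"
        )
    if paired:
        if curve1.n_cases != curve2.n_cases or curve1.n_controls != curve2.n_controls:
            raise InvalidInputError("paired comparison requires equal class sizes")
        if (
            curve1.response is not None
            and curve2.response is not None
            and not are_paired(curve1, curve2)
        ):
            raise InvalidInputError(
                "curves have different response vectors; not a paired design"
            )


def delong_test(
    curve1: ROCCurve,
    curve2: ROCCurve,
    paired: bool = True,
    alternative: str = "two_sided",
) -> TestResult:
    """DeLong's U-statistic test for the difference of two AUCs.

    The variance of theta1 - theta2 combines the sample covariance matrices
    of the paired placement values; for unpaired curves the cross terms
    vanish and the variance is the sum of the two single-curve variances.
    """
    _check_comparable(curve1, curve2, paired)
    p1 = delong_placements(curve1)
    p2 = delong_placements(curve2)
    m1, n1 = curve1.n_cases, curve1.n_controls
    m2, n2 = curve2.n_cases, curve2.n_controls
    if paired:
        s10 = np.cov(p1.v10, p2.v10, ddof=1)
        s01 = np.cov(p1.v01, p2.v01, ddof=1)
        var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m1 + (
            s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
        ) / n1
        method = "DeLong paired test"
    else:
        var = (
            np.var(p1.v10, ddof=1) / m1
            + np.var(p1.v01, ddof=1) / n1
            + np.var(p2.v10, ddof=1) / m2
            + np.var(p2.v01, ddof=1) / n2
        )
        method = "DeLong unpaired test"
    diff = p1.theta - p2.theta
    if var <= 0:
        if diff == 0:
            return TestResult(0.0, 1.0, alternative, method,
                              estimates=(p1.theta, p2.theta), degenerate=True)
        raise EstimationError("zero DeLong variance with unequal AUCs")
    z = diff / np.sqrt(var)
    return TestResult(
        float(z), _normal_p(z, alternative), alternative, method,
        estimates=(p1.theta, p2.theta),
    )


# ---------------------------------------------------------------------------
# Bootstrap machinery


def _metric_fn(metric: str, prange: Optional[PartialRange],
               smooth_method: str, smooth_options: dict):
    """Return f(cases, controls, direction) -> float for a curve metric.

    The returned callable rebuilds the curve from raw samples, which is what
    each bootstrap replicate needs.
    """
    if metric == "auc":
        def f(cases, controls, direction):
            if direction == "controls_higher":
                return _mw_auc(-cases, -controls)
            return _mw_auc(cases, controls)
        return f
    if metric == "pauc":
        if prange is None:
            raise InvalidInputError("metric='pauc' requires a partial range")
        def f(cases, controls, direction):
            _, sp, se = _curve_points(cases, controls, direction)
            raw = _area_arrays(sp, se, prange)
            if prange.standardize:
                mn, mx = prange.chance_area(), prange.perfect_area()
                return 0.5 * (1.0 + (raw - mn) / (mx - mn))
            return raw
        return f
    if metric == "smoothed_auc":
        from . import smoothing  # local import to keep module load light

        def f(cases, controls, direction):
            sm = smoothing.smooth_samples(
                cases, controls, direction, method=smooth_method, **smooth_options
            )
            return float(sm.auc())
        return f
    raise InvalidInputError(f"unknown metric {metric!r}")


def _bootstrap_diffs(
    curve1: ROCCurve,
    curve2: ROCCurve,
    metric: str,
    prange: Optional[PartialRange],
    plan: ResamplePlan,
    smooth_method: str,
    smooth_options: dict,
) -> np.ndarray:
    """Replicate-wise metric differences D_r = theta1_r - theta2_r."""
    rng = plan.rng()
    if (
        metric == "auc"
        and plan.stratified
        and curve1.direction == curve2.direction
    ):
        return _fast_auc_diffs(curve1, curve2, plan, rng)
    fn = _metric_fn(metric, prange, smooth_method, smooth_options)
    d = np.empty(plan.n_replicates)
    if plan.paired:
        pairs = resample_index_pairs(curve1.n_cases, curve1.n_controls, plan, rng)
        for r, (ci, ni) in enumerate(pairs):
            t1 = fn(curve1.cases[ci], curve1.controls[ni], curve1.direction)
            t2 = fn(curve2.cases[ci], curve2.controls[ni], curve2.direction)
            d[r] = t1 - t2
    else:
        pairs1 = list(resample_index_pairs(curve1.n_cases, curve1.n_controls, plan, rng))
        pairs2 = list(resample_index_pairs(curve2.n_cases, curve2.n_controls, plan, rng))
        for r in range(plan.n_replicates):
            ci, ni = pairs1[r]
            cj, nj = pairs2[r]
            t1 = fn(curve1.cases[ci], curve1.controls[ni], curve1.direction)
            t2 = fn(curve2.cases[cj], curve2.controls[nj], curve2.direction)
            d[r] = t1 - t2
    return d


def _batch_auc(cases_mat: np.ndarray, controls_mat: np.ndarray) -> np.ndarray:
    """Row-wise Mann-Whitney AUC for oriented replicate matrices."""
    m = cases_mat.shape[1]
    n = controls_mat.shape[1]
    pooled = np.concatenate([cases_mat, controls_mat], axis=1)
    ranks = stats.rankdata(pooled, method="average", axis=1)
    return (ranks[:, :m].sum(axis=1) - m * (m + 1) / 2.0) / (m * n)


def _fast_auc_diffs(
    curve1: ROCCurve, curve2: ROCCurve, plan: ResamplePlan, rng: np.random.Generator
) -> np.ndarray:
    b = plan.n_replicates
    c1, n1 = curve1.oriented()
    c2, n2 = curve2.oriented()
    if plan.paired:
        ic = rng.integers(0, c1.size, (b, c1.size))
        ii = rng.integers(0, n1.size, (b, n1.size))
        a1 = _batch_auc(c1[ic], n1[ii])
        a2 = _batch_auc(c2[ic], n2[ii])
    else:
        ic1 = rng.integers(0, c1.size, (b, c1.size))
        ii1 = rng.integers(0, n1.size, (b, n1.size))
        ic2 = rng.integers(0, c2.size, (b, c2.size))
        ii2 = rng.integers(0, n2.size, (b, n2.size))
        a1 = _batch_auc(c1[ic1], n1[ii1])
        a2 = _batch_auc(c2[ic2], n2[ii2])
    return a1 - a2


def bootstrap_test(
    curve1: ROCCurve,
    curve2: ROCCurve,
    metric: str = "auc",
    prange: Optional[PartialRange] = None,
    plan: Optional[ResamplePlan] = None,
    alternative: str = "two_sided",
    smooth_method: str = "binormal",
    smooth_options: Optional[dict] = None,
) -> TestResult:
    """Bootstrap Z-test on the difference of a curve metric.

    Z = (theta1 - theta2) / sd(D) where theta are the metrics of the
    original curves and D the replicate-wise differences; the p-value comes
    from the normal distribution.  Works for total AUC, partial AUC (pass a
    range) and smoothed AUC (each replicate is re-smoothed).
    """
    if plan is None:
        plan = ResamplePlan()
    _check_comparable(curve1, curve2, plan.paired)
    smooth_options = dict(smooth_options or {})
    fn = _metric_fn(metric, prange, smooth_method, smooth_options)
    t1 = fn(curve1.cases, curve1.controls, curve1.direction)
    t2 = fn(curve2.cases, curve2.controls, curve2.direction)
    d = _bootstrap_diffs(curve1, curve2, metric, prange, plan,
                         smooth_method, smooth_options)
    d = d[np.isfinite(d)]
    if d.size < 2:
        raise EstimationError("too few valid bootstrap replicates")
    sd = float(np.std(d, ddof=1))
    diff = t1 - t2
    method = f"bootstrap {'paired' if plan.paired else 'unpaired'} test ({metric})"
    if sd == 0.0:
        if diff == 0.0:
            return TestResult(0.0, 1.0, alternative, method, n_resamples=d.size,
                              estimates=(t1, t2), degenerate=True, seed=plan.seed)
        raise EstimationError("zero bootstrap variance with unequal metrics")
    z = diff / sd
    return TestResult(
        float(z), _normal_p(z, alternative), alternative, method,
        n_resamples=int(d.size), estimates=(float(t1), float(t2)), seed=plan.seed,
    )


def fixed_point_test(
    curve1: ROCCurve,
    curve2: ROCCurve,
    at: float,
    axis: str = "specificity",
    plan: Optional[ResamplePlan] = None,
    alternative: str = "two_sided",
) -> TestResult:
    """Bootstrap test of the curves at a fixed operating point.

    Compares the interpolated sensitivity at a given specificity (or the
    converse); equivalent to a partial-AUC test over a vanishing range.
    """
    if not (0.0 < at < 1.0):
        raise InvalidInputError("operating point must be strictly inside (0, 1)")
    if axis not in ("specificity", "sensitivity"):
        raise InvalidInputError(f"unknown axis {axis!r}")
    if plan is None:
        plan = ResamplePlan()
    _check_comparable(curve1, curve2, plan.paired)

    def conj(cases, controls, direction):
        _, sp, se = _curve_points(cases, controls, direction)
        if axis == "specificity":
            return float(_interp_conjugate(sp, se, at))
        return float(_interp_conjugate(se[::-1], sp[::-1], at))

    t1 = conj(curve1.cases, curve1.controls, curve1.direction)
    t2 = conj(curve2.cases, curve2.controls, curve2.direction)
    rng = plan.rng()
    d = np.empty(plan.n_replicates)
    if plan.paired:
        pairs = resample_index_pairs(curve1.n_cases, curve1.n_controls, plan, rng)
        for r, (ci, ni) in enumerate(pairs):
            d[r] = conj(curve1.cases[ci], curve1.controls[ni], curve1.direction) - conj(
                curve2.cases[ci], curve2.controls[ni], curve2.direction
            )
    else:
        pairs1 = list(resample_index_pairs(curve1.n_cases, curve1.n_controls, plan, rng))
        pairs2 = list(resample_index_pairs(curve2.n_cases, curve2.n_controls, plan, rng))
        for r in range(plan.n_replicates):
            ci, ni = pairs1[r]
            cj, nj = pairs2[r]
            d[r] = conj(curve1.cases[ci], curve1.controls[ni], curve1.direction) - conj(
                curve2.cases[cj], curve2.controls[nj], curve2.direction
            )
    sd = float(np.std(d, ddof=1))
    conj_name = "sensitivity" if axis == "specificity" else "specificity"
    method = f"bootstrap fixed-point test ({conj_name} at {axis}={at:g})"
    diff = t1 - t2
    if sd == 0.0:
        if diff == 0.0:
            return TestResult(0.0, 1.0, alternative, method,
                              n_resamples=plan.n_replicates,
                              estimates=(t1, t2), degenerate=True, seed=plan.seed)
        raise EstimationError("zero bootstrap variance with unequal coordinates")
    z = diff / sd
    return TestResult(float(z), _normal_p(z, alternative), alternative, method,
                      n_resamples=plan.n_replicates, estimates=(t1, t2),
                      seed=plan.seed)


# ---------------------------------------------------------------------------
# Venkatraman permutation tests

_JITTER = 0.5  # strictly below the minimal gap between distinct midranks


def _orient(values: np.ndarray, is_case: np.ndarray, direction: str) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if direction == "auto":
        direction = (
            "controls_lower"
            if np.median(values[~is_case]) <= np.median(values[is_case])
            else "controls_higher"
        )
    return -values if direction == "controls_higher" else values


def _error_curve_midrank(ranks: np.ndarray, is_case: np.ndarray) -> np.ndarray:
    """Misclassification counts e(k), k = 1..N-1, calling positive above rank k."""
    n = ranks.size
    n_ctrl = int(np.sum(~is_case))
    ks = np.arange(1, n)[:, None]
    fn = np.sum((ranks[None, :] <= ks) & is_case[None, :], axis=1)
    fp = n_ctrl - np.sum((ranks[None, :] <= ks) & ~is_case[None, :], axis=1)
    return fn + fp


def _rerank_rows(values: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Row-wise orderings after random tie-breaking.

    Adds U(0, 0.5) jitter (strictly below the minimal distinct-midrank gap)
    and argsorts, so tied entries are ordered uniformly at random while the
    order of distinct entries is preserved.  Returns argsort indices.
    """
    return np.argsort(values + _JITTER * u, axis=1, kind="stable")


def _paired_perm_stats(
    r_x: np.ndarray,
    r_y: np.ndarray,
    is_case: np.ndarray,
    swap: np.ndarray,
    u_x: np.ndarray,
    u_y: np.ndarray,
) -> np.ndarray:
    """Permutation statistics for explicit swap patterns and tie-break draws.

    For each row b, marker ranks are exchanged per subject where
    ``swap[b]`` is True, re-ranked with random tie-breaking, and the
    statistic E = sum_k |e_x(k) - e_y(k)| computed over rank cut-offs
    k = 1..N-1.  With integer re-ranks this reduces to twice the summed
    absolute difference of cumulative case counts in rank order.
    """
    rx2 = np.where(swap, r_y, r_x)
    ry2 = np.where(swap, r_x, r_y)
    ox = _rerank_rows(rx2, u_x)
    oy = _rerank_rows(ry2, u_y)
    case_f = is_case.astype(np.int64)
    cum_x = np.cumsum(case_f[ox], axis=1)[:, :-1]
    cum_y = np.cumsum(case_f[oy], axis=1)[:, :-1]
    return 2.0 * np.sum(np.abs(cum_x - cum_y), axis=1)


def _unpaired_stat(
    r1: np.ndarray, case1: np.ndarray, r2: np.ndarray, case2: np.ndarray
) -> float:
    """Integrated |e1(p) - e2(p)| over the cut-off fraction p in (0, 1).

    Each sample's misclassification fraction e(p) = (FN + FP) / N is a step
    function changing at p = k/N; the integral is taken over the union grid
    of both samples' step points.
    """
    def err_fracs(ranks, is_case):
        n = ranks.size
        order = np.argsort(ranks, kind="stable")
        cum_case = np.concatenate([[0], np.cumsum(is_case[order])])
        ks = np.arange(n + 1)
        n_ctrl = int(np.sum(~is_case))
        e = 2 * cum_case - ks + n_ctrl  # FN(k) + FP(k) at integer cut-off k
        return e / n

    e1 = err_fracs(r1, case1)
    e2 = err_fracs(r2, case2)
    n1, n2 = r1.size, r2.size
    grid = np.union1d(np.arange(n1 + 1) / n1, np.arange(n2 + 1) / n2)
    mid = 0.5 * (grid[:-1] + grid[1:])
    w = np.diff(grid)
    v1 = e1[np.floor(mid * n1).astype(int)]
    v2 = e2[np.floor(mid * n2).astype(int)]
    return float(np.sum(w * np.abs(v1 - v2)))


def venkatraman_test(
    marker1,
    marker2,
    response,
    paired: bool = True,
    n_permutations: int = 2000,
    seed: Optional[int] = None,
    response2=None,
    direction: str = "auto",
    exhaustive: bool = False,
    positive_label=None,
) -> TestResult:
    """Venkatraman's permutation test on the shape of two ROC curves.

    Paired design (both markers on the same subjects): the statistic is the
    summed absolute difference of the two markers' misclassification counts
    over all rank cut-offs; the null is generated by swapping the two
    markers' ranks within random subject subsets, re-ranking with random
    tie-breaking.  ``exhaustive=True`` enumerates all 2^N swap patterns
    instead of sampling (small N only).

    Unpaired design: two independent samples, ``response2`` labelling the
    second; the statistic integrates the misclassification-fraction
    difference over cut-off quantiles, and permutations exchange
    rank-transformed subjects between the samples within each class.
    """
    if n_permutations < 1 and not exhaustive:
        raise InvalidInputError("n_permutations must be >= 1")
    response = np.asarray(response)
    from .curve import _resolve_labels

    y1 = _resolve_labels(response, positive_label)
    is_case1 = y1 == 1
    rng = np.random.default_rng(seed)

    if paired:
        marker1 = np.asarray(marker1, dtype=float)
        marker2 = np.asarray(marker2, dtype=float)
        if marker1.shape != marker2.shape or marker1.shape != response.shape:
            raise InvalidInputError("paired test requires aligned markers and response")
        x = _orient(marker1, is_case1, direction)
        y = _orient(marker2, is_case1, direction)
        n = x.size
        r_x = stats.rankdata(x)
        r_y = stats.rankdata(y)
        e_obs = float(
            np.sum(np.abs(_error_curve_midrank(r_x, is_case1)
                          - _error_curve_midrank(r_y, is_case1)))
        )
        if exhaustive:
            if n > 20:
                raise InvalidInputError("exhaustive enumeration limited to N <= 20")
            b = 2 ** n
            patterns = (
                (np.arange(b)[:, None] >> np.arange(n)[None, :]) & 1
            ).astype(bool)
        else:
            b = n_permutations
            patterns = rng.random((b, n)) < 0.5
        u_x = rng.random((b, n))
        u_y = rng.random((b, n))
        null = _paired_perm_stats(r_x, r_y, is_case1, patterns, u_x, u_y)
        p = empirical_pvalue(null, e_obs, "greater")
        method = "Venkatraman paired permutation test" + (
            " (exhaustive)" if exhaustive else ""
        )
        return TestResult(e_obs, p, "greater", method, n_resamples=int(b), seed=seed)

    # unpaired
    if response2 is None:
        raise InvalidInputError("unpaired test requires response2 for marker2")
    response2 = np.asarray(response2)
    y2 = _resolve_labels(response2, positive_label)
    is_case2 = y2 == 1
    marker1 = np.asarray(marker1, dtype=float)
    marker2 = np.asarray(marker2, dtype=float)
    if marker1.shape != response.shape or marker2.shape != response2.shape:
        raise InvalidInputError("markers must align with their response vectors")
    x = _orient(marker1, is_case1, direction)
    y = _orient(marker2, is_case2, direction)
    r1 = stats.rankdata(x)
    r2 = stats.rankdata(y)
    e_obs = _unpaired_stat(r1, is_case1, r2, is_case2)
    # rank-transform to a shared [0, 1] scale so subjects are exchangeable
    u1 = r1 / (r1.size + 1)
    u2 = r2 / (r2.size + 1)
    case_pool = np.concatenate([u1[is_case1], u2[is_case2]])
    ctrl_pool = np.concatenate([u1[~is_case1], u2[~is_case2]])
    m1 = int(is_case1.sum())
    c1 = int((~is_case1).sum())
    null = np.empty(n_permutations)
    for r in range(n_permutations):
        cp = rng.permutation(case_pool)
        np_ = rng.permutation(ctrl_pool)
        s1 = np.concatenate([cp[:m1], np_[:c1]])
        s2 = np.concatenate([cp[m1:], np_[c1:]])
        lab1 = np.concatenate([np.ones(m1, bool), np.zeros(c1, bool)])
        lab2 = np.concatenate(
            [np.ones(cp.size - m1, bool), np.zeros(np_.size - c1, bool)]
        )
        rr1 = _rank_random_ties(s1, rng)
        rr2 = _rank_random_ties(s2, rng)
        null[r] = _unpaired_stat(rr1, lab1, rr2, lab2)
    p = empirical_pvalue(null, e_obs, "greater")
    return TestResult(
        e_obs, p, "greater", "Venkatraman unpaired permutation test",
        n_resamples=n_permutations, seed=seed,
    )


def _rank_random_ties(values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Integer ranks 1..N with ties broken uniformly at random."""
    order = np.lexsort((rng.random(values.size), values))
    ranks = np.empty(values.size)
    ranks[order] = np.arange(1, values.size + 1)
    return ranks
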