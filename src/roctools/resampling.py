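"""Bootstrap and permutation plumbing shared by all tests and intervals.

Resampling is stratified by default: each replicate redraws exactly the
observed number of cases and of controls, with replacement, within class.
Non-stratified resampling redraws subjects regardless of label; replicates
that lose an entire class are discarded and redrawn (the count is recorded
on the plan).  All randomness flows from a single integer root seed through
one `numpy` Generator, so every downstream statistic is reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterator, Optional

import numpy as np

from .errors import EstimationError, InvalidInputError

__all__ = [
    "ResamplePlan",
    "stratified_resample",
    "resample_index_pairs",
    "percentile_interval",
    "empirical_pvalue",
]


@dataclass
class ResamplePlan:
    """How to resample: replicate count, stratification, pairing, seed.

    ``paired`` means the two markers being compared were measured on the
    same subjects, so each replicate draws one set of subject indices and
    both markers follow it (preserving within-subject correlation).
    """

    n_replicates: int = 2000
    stratified: bool = True
    seed: Optional[int] = None
    paired: bool = False
    progress: Optional[Callable[[int, int], None]] = None  # (done, total)
    n_redrawn: int = field(default=0, init=False, repr=False)

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise InvalidInputError("n_replicates must be >= 1")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def resample_index_pairs(
    m: int, n: int, plan: ResamplePlan, rng: np.random.Generator
) -> Iterator[tuple[np.ndarray, np.ndarray]]:
    """Yield per-replicate (case_indices, control_indices) drawn by ``plan``.

    Case indices address 0..m-1, control indices 0..n-1.  Non-stratified
    draws sample m+n subjects from the pooled index space 0..m+n-1 (cases
    first) and split by label afterwards; single-class replicates are
    redrawn and counted in ``plan.n_redrawn``.
    """
    total = m + n
    for r in range(plan.n_replicates):
        if plan.stratified:
            yield rng.integers(0, m, m), rng.integers(0, n, n)
        else:
            while True:
                pooled = rng.integers(0, total, total)
                ci = pooled[pooled < m]
                ni = pooled[pooled >= m] - m
                if ci.size and ni.size:
                    break
                plan.n_redrawn += 1
            yield ci, ni
        if plan.progress is not None:
            plan.progress(r + 1, plan.n_replicates)


def stratified_resample(
    cases: np.ndarray,
    controls: np.ndarray,
    plan: ResamplePlan,
    rng: Optional[np.random.Generator] = None,
) -> Iterator[tuple[np.ndarray, np.ndarray]]:
    """Yield resampled (cases, controls) value arrays, one pair per replicate."""
    cases = np.asarray(cases, dtype=float)
    controls = np.asarray(controls, dtype=float)
    if cases.size == 0 or controls.size == 0:
        raise InvalidInputError("both classes must be non-empty")
    if rng is None:
        rng = plan.rng()
    for ci, ni in resample_index_pairs(cases.size, controls.size, plan, rng):
        yield cases[ci], controls[ni]


def percentile_interval(samples, level: float = 0.95) -> tuple[float, float]:
    """Equal-tailed bootstrap percentile interval of a replicate distribution.

    Uses the linear-interpolation quantile definition.  Non-finite
    replicates are dropped with a warning.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise InvalidInputError("empty replicate sample")
    if not (0.0 < level < 1.0):
        raise InvalidInputError("level must be in (0, 1)")
    finite = samples[np.isfinite(samples)]
    if finite.size == 0:
        raise EstimationError("all replicate values are non-finite")
    if finite.size < samples.size:
        warnings.warn(
            f"dropped {samples.size - finite.size} non-finite replicate(s)",
            stacklevel=2,
        )
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(finite, [alpha, 1.0 - alpha], method="linear")
    return float(lo), float(hi)


def empirical_pvalue(
    null_stats, observed: float, alternative: str = "greater"
) -> float:
    """Raw proportion of null statistics at least as extreme as observed.

    ``greater``: P(null >= observed); ``two_sided``: P(|null| >= |observed|).
    A zero proportion means the observed statistic exceeded every null draw
    and should be reported as "< 1/N" by the caller.
    """
    null_stats = np.asarray(null_stats, dtype=float)
    if null_stats.size == 0:
        raise InvalidInputError("empty null distribution")
    if alternative == "greater":
        return float(np.mean(null_stats >= observed))
    if alternative == "two_sided":
        return float(np.mean(np.abs(null_stats) >= abs(observed)))
    raise InvalidInputError(f"unknown alternative {alternative!r}")
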