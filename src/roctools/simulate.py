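"""Synthetic biomarker data with known ROC properties.

The generators emulate the structure of a typical clinical biomarker study:
a cohort with a binary outcome (here defaulting to 141 subjects, 41 cases /
100 controls, the size and roughly the case prevalence of an aneurysmal
subarachnoid haemorrhage outcome cohort), one or two continuous markers
drawn from class-conditional normal distributions, and ordinal clinical
scores (like the 1-5 WFNS grade) obtained by discretising a latent
continuous marker through cut-points.

Paired markers use a latent-Gaussian construction: within each class the
two markers are bivariate normal with correlation ``rho``, which makes the
joint distribution fully controllable while keeping the marginals — and
hence each marker's true ROC curve — in closed form:

    AUC = Phi((mu_case - mu_control) / sqrt(sigma_case^2 + sigma_control^2))

True (partial) areas reported by the helpers are computed from this
binormal form, not from the samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import integrate, stats

from .errors import InvalidInputError

__all__ = [
    "BinormalSpec",
    "SimulatedSample",
    "binormal_sample",
    "ordinal_sample",
    "null_pair_sample",
    "binormal_auc",
    "binormal_pauc",
]


@dataclass(frozen=True)
class BinormalSpec:
    """Class-conditional normal model for one or two (paired) markers.

    The second marker shares ``rho`` (within-class correlation) and has its
    own means/SDs, defaulting to the first marker's — i.e. to an exact null
    in which both markers have the same true ROC curve.
    """

    mu_case: float = 1.0
    mu_control: float = 0.0
    sigma_case: float = 1.0
    sigma_control: float = 1.0
    n_case: int = 41
    n_control: int = 100
    rho: float = 0.5
    seed: Optional[int] = None
    mu_case2: Optional[float] = None
    mu_control2: Optional[float] = None
    sigma_case2: Optional[float] = None
    sigma_control2: Optional[float] = None

    def __post_init__(self) -> None:
        if self.sigma_case <= 0 or self.sigma_control <= 0:
            raise InvalidInputError("sigmas must be positive")
        if not (-1.0 <= self.rho <= 1.0):
            raise InvalidInputError("rho must lie in [-1, 1]")
        if self.n_case < 1 or self.n_control < 1:
            raise InvalidInputError("class sizes must be positive")

    @property
    def marker2_params(self) -> tuple[float, float, float, float]:
        return (
            self.mu_case if self.mu_case2 is None else self.mu_case2,
            self.mu_control if self.mu_control2 is None else self.mu_control2,
            self.sigma_case if self.sigma_case2 is None else self.sigma_case2,
            self.sigma_control if self.sigma_control2 is None else self.sigma_control2,
        )

    def true_auc(self, marker: int = 1) -> float:
        if marker == 1:
            return binormal_auc(
                self.mu_case, self.mu_control, self.sigma_case, self.sigma_control
            )
        return binormal_auc(*self.marker2_params)

    def true_pauc(
        self, lo: float, hi: float, axis: str = "specificity", marker: int = 1
    ) -> float:
        if marker == 1:
            mc, mn, sc, sn = (
                self.mu_case, self.mu_control, self.sigma_case, self.sigma_control
            )
        else:
            mc, mn, sc, sn = self.marker2_params
        a = (mc - mn) / sc
        b = sn / sc
        return binormal_pauc(a, b, lo, hi, axis=axis)


def binormal_auc(
    mu_case: float, mu_control: float, sigma_case: float, sigma_control: float
) -> float:
    """Closed-form AUC of the binormal model."""
    return float(
        stats.norm.cdf(
            (mu_case - mu_control) / np.hypot(sigma_case, sigma_control)
        )
    )


def binormal_pauc(
    a: float, b: float, lo: float, hi: float, axis: str = "specificity"
) -> float:
    """Partial area of the binormal curve se(sp) = Phi(a + b Phi^-1(1-sp)).

    Evaluated by adaptive quadrature of the exact integrand over the
    requested window (specificity axis: integral of se d(sp); sensitivity
    axis: integral of sp d(se), using the inverse relation).
    """
    if axis == "specificity":
        def f(sp):
            return stats.norm.cdf(a + b * stats.norm.ppf(1.0 - sp))
    elif axis == "sensitivity":
        def f(se):
            return stats.norm.cdf(-(stats.norm.ppf(se) - a) / b)
    else:
        raise InvalidInputError(f"unknown axis {axis!r}")
    val, _ = integrate.quad(f, lo, hi, limit=200)
    return float(val)


@dataclass(frozen=True)
class SimulatedSample:
    """A simulated cohort: labels, marker(s), and the generating truth."""

    response: np.ndarray
    marker1: np.ndarray
    marker2: Optional[np.ndarray]
    spec: BinormalSpec

    @property
    def true_auc1(self) -> float:
        return self.spec.true_auc(1)

    @property
    def true_auc2(self) -> float:
        return self.spec.true_auc(2)

    def to_frame(self) -> pd.DataFrame:
        data = {"outcome": self.response, "marker1": self.marker1}
        if self.marker2 is not None:
            data["marker2"] = self.marker2
        return pd.DataFrame(data)


def binormal_sample(
    spec: BinormalSpec, paired: bool = False,
    rng: Optional[np.random.Generator] = None,
) -> SimulatedSample:
    """Draw a cohort from the binormal model.

    With ``paired=True`` a second marker is drawn jointly with within-class
    correlation ``spec.rho`` and its own class means/SDs.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    response = np.concatenate(
        [np.ones(spec.n_case, dtype=int), np.zeros(spec.n_control, dtype=int)]
    )
    if not paired:
        cases = rng.normal(spec.mu_case, spec.sigma_case, spec.n_case)
        controls = rng.normal(spec.mu_control, spec.sigma_control, spec.n_control)
        return SimulatedSample(response, np.concatenate([cases, controls]), None, spec)
    mc2, mn2, sc2, sn2 = spec.marker2_params
    z_case = _bivariate(rng, spec.n_case, spec.rho)
    z_ctrl = _bivariate(rng, spec.n_control, spec.rho)
    m1 = np.concatenate(
        [
            spec.mu_case + spec.sigma_case * z_case[:, 0],
            spec.mu_control + spec.sigma_control * z_ctrl[:, 0],
        ]
    )
    m2 = np.concatenate(
        [mc2 + sc2 * z_case[:, 1], mn2 + sn2 * z_ctrl[:, 1]]
    )
    return SimulatedSample(response, m1, m2, spec)


def _bivariate(rng: np.random.Generator, n: int, rho: float) -> np.ndarray:
    z1 = rng.standard_normal(n)
    z2 = rho * z1 + np.sqrt(max(0.0, 1.0 - rho**2)) * rng.standard_normal(n)
    return np.column_stack([z1, z2])


def ordinal_sample(
    levels: int,
    cutpoints: Sequence[float],
    spec: BinormalSpec,
    rng: Optional[np.random.Generator] = None,
) -> SimulatedSample:
    """Ordinal clinical score: a latent binormal marker cut into 1..levels."""
    cutpoints = np.asarray(cutpoints, dtype=float)
    if cutpoints.size != levels - 1:
        raise InvalidInputError("need levels - 1 cutpoints")
    if np.any(np.diff(cutpoints) <= 0):
        raise InvalidInputError("cutpoints must be strictly increasing")
    latent = binormal_sample(spec, paired=False, rng=rng)
    score = np.searchsorted(cutpoints, latent.marker1) + 1
    return SimulatedSample(latent.response, score.astype(float), latent.marker1, spec)


def null_pair_sample(
    spec: BinormalSpec, rng: Optional[np.random.Generator] = None
) -> SimulatedSample:
    """Paired markers with identical class-conditional marginals (exact null)."""
    null_spec = BinormalSpec(
        mu_case=spec.mu_case,
        mu_control=spec.mu_control,
        sigma_case=spec.sigma_case,
        sigma_control=spec.sigma_control,
        n_case=spec.n_case,
        n_control=spec.n_control,
        rho=spec.rho,
        seed=spec.seed,
    )
    return binormal_sample(null_spec, paired=True, rng=rng)
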