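import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import roctools as rt

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture
def toy_curve():
    """controls {1,2,4} vs cases {3,5,7}: 7 points, AUC 8/9."""
    return rt.roc_from_samples([3, 5, 7], [1, 2, 4])


@pytest.fixture
def perfect_curve():
    return rt.roc_from_samples([4, 5, 6], [1, 2, 3])


@pytest.fixture
def chance_curve():
    """Identical class samples: the empirical curve lies on the diagonal."""
    return rt.roc_from_samples([1, 2, 3], [1, 2, 3])


@pytest.fixture
def paired_cohort():
    """A correlated null pair of markers on 50+50 subjects, with curves."""
    spec = rt.BinormalSpec(mu_case=1.19, n_case=50, n_control=50, rho=0.5, seed=42)
    s = rt.null_pair_sample(spec)
    c1 = rt.build_roc(s.response, s.marker1, positive_label=1,
                      direction="controls_lower")
    c2 = rt.build_roc(s.response, s.marker2, positive_label=1,
                      direction="controls_lower")
    return s, c1, c2


def random_small_samples(rng, max_n=30):
    """A random small case/control pair, possibly with ties (integer grid)."""
    m = int(rng.integers(1, max_n))
    n = int(rng.integers(1, max_n))
    if rng.random() < 0.5:  # force ties through a coarse grid
        cases = rng.integers(0, 8, m).astype(float)
        controls = rng.integers(0, 8, n).astype(float)
    else:
        cases = rng.normal(1, 1, m)
        controls = rng.normal(0, 1, n)
    return cases, controls


def brute_force_auc(cases, controls, direction="controls_lower"):
    """O(mn) Mann-Whitney count with ties 1/2 — independent AUC oracle."""
    if direction == "controls_higher":
        cases, controls = -np.asarray(cases), -np.asarray(controls)
    total = 0.0
    for c in np.asarray(cases):
        for n in np.asarray(controls):
            if c > n:
                total += 1.0
            elif c == n:
                total += 0.5
    return total / (len(cases) * len(controls))
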