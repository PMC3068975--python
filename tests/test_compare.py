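"""Comparison tests: DeLong, bootstrap, Venkatraman, fixed operating point."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import roctools as rt
from roctools.compare import _error_curve_midrank, _paired_perm_stats
from roctools.errors import EstimationError, InvalidInputError

from conftest import brute_force_auc, random_small_samples


def brute_placements(cases, controls):
    """Direct psi-table enumeration of DeLong placements (independent oracle)."""
    cases, controls = np.asarray(cases, float), np.asarray(controls, float)
    psi = np.where(
        cases[:, None] > controls[None, :], 1.0,
        np.where(cases[:, None] == controls[None, :], 0.5, 0.0),
    )
    return psi.mean(axis=1), psi.mean(axis=0)


class TestPlacements:
    def test_toy_psi_table(self, toy_curve):
        pl = rt.delong_placements(toy_curve)
        np.testing.assert_allclose(pl.v10, [2 / 3, 1, 1])
        np.testing.assert_allclose(pl.v01, [1, 1, 2 / 3])
        assert pl.theta == pytest.approx(8 / 9)

    def test_perfect_and_tied_extremes(self, perfect_curve, chance_curve):
        pl = rt.delong_placements(perfect_curve)
        assert np.all(pl.v10 == 1) and np.all(pl.v01 == 1) and pl.theta == 1
        assert rt.delong_placements(chance_curve).theta == 0.5

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 10_000))
    def test_means_equal_trapezoidal_auc(self, seed):
        rng = np.random.default_rng(seed)
        cases, controls = random_small_samples(rng)
        curve = rt.roc_from_samples(cases, controls, direction="controls_lower")
        pl = rt.delong_placements(curve)
        v10, v01 = brute_placements(cases, controls)
        np.testing.assert_allclose(pl.v10, v10, atol=1e-12)
        np.testing.assert_allclose(pl.v01, v01, atol=1e-12)
        assert pl.v10.mean() == pytest.approx(float(curve.auc()), abs=1e-12)
        assert pl.v01.mean() == pytest.approx(float(curve.auc()), abs=1e-12)


def delong_brute_force(resp, m1, m2, paired):
    """Variance/Z of the AUC difference from enumerated placements."""
    m1, m2 = np.asarray(m1, float), np.asarray(m2, float)
    resp = np.asarray(resp)
    v10_1, v01_1 = brute_placements(m1[resp == 1], m1[resp == 0])
    v10_2, v01_2 = brute_placements(m2[resp == 1], m2[resp == 0])
    t1, t2 = v10_1.mean(), v10_2.mean()
    m, n = v10_1.size, v01_1.size

    def cov(a, b):
        return float(np.sum((a - a.mean()) * (b - b.mean())) / (a.size - 1))

    if paired:
        var = (cov(v10_1, v10_1) + cov(v10_2, v10_2) - 2 * cov(v10_1, v10_2)) / m
        var += (cov(v01_1, v01_1) + cov(v01_2, v01_2) - 2 * cov(v01_1, v01_2)) / n
    else:
        var = cov(v10_1, v10_1) / m + cov(v01_1, v01_1) / n
        var += cov(v10_2, v10_2) / m + cov(v01_2, v01_2) / n
    return (t1 - t2) / np.sqrt(var)


class TestDeLong:
    def test_self_comparison_degenerate(self, toy_curve):
        res = rt.delong_test(toy_curve, toy_curve, paired=True)
        assert res.p_value == 1.0

    def test_paired_toy_matches_enumeration(self):
        resp = [0, 0, 0, 0, 1, 1, 1, 1]
        m1 = [1.0, 2.0, 4.0, 4.5, 3.0, 5.0, 7.0, 8.0]
        m2 = [1.0, 2.0, 4.0, 6.0, 7.0, 5.0, 3.0, 8.0]
        c1 = rt.build_roc(resp, m1, positive_label=1, direction="controls_lower")
        c2 = rt.build_roc(resp, m2, positive_label=1, direction="controls_lower")
        res = rt.delong_test(c1, c2, paired=True)
        z = delong_brute_force(resp, m1, m2, paired=True)
        assert res.statistic == pytest.approx(z, abs=1e-12)
        assert res.p_value == pytest.approx(2 * stats.norm.sf(abs(z)), abs=1e-12)

    def test_unpaired_variance_is_sum_of_single_curve_variances(self):
        rng = np.random.default_rng(5)
        c1 = rt.roc_from_samples(rng.normal(1, 1, 20), rng.normal(0, 1, 25),
                                 direction="controls_lower")
        c2 = rt.roc_from_samples(rng.normal(0.5, 1, 15), rng.normal(0, 1, 30),
                                 direction="controls_lower")
        res = rt.delong_test(c1, c2, paired=False)
        resp1 = np.r_[np.ones(20, int), np.zeros(25, int)]
        # reuse the oracle: unpaired formula ignores cross terms entirely
        z = (float(c1.auc()) - float(c2.auc()))
        var = 0.0
        for c in (c1, c2):
            v10, v01 = brute_placements(c.cases, c.controls)
            var += np.var(v10, ddof=1) / v10.size + np.var(v01, ddof=1) / v01.size
        assert res.statistic == pytest.approx(z / np.sqrt(var), abs=1e-12)

    def test_alternatives_consistent(self, paired_cohort):
        _, c1, c2 = paired_cohort
        two = rt.delong_test(c1, c2, paired=True, alternative="two_sided")
        gt = rt.delong_test(c1, c2, paired=True, alternative="greater")
        lt = rt.delong_test(c1, c2, paired=True, alternative="less")
        assert gt.p_value + lt.p_value == pytest.approx(1.0)
        assert two.p_value == pytest.approx(2 * min(gt.p_value, lt.p_value))

    def test_zero_variance_with_unequal_aucs_is_error(self):
        c1 = rt.roc_from_samples([4, 5, 6], [1, 2, 3], direction="controls_lower")
        c2 = rt.roc_from_samples([1, 2, 3], [4, 5, 6], direction="controls_lower")
        with pytest.raises(EstimationError):
            rt.delong_test(c1, c2, paired=False)

    def test_opposite_directions_refused(self):
        c1 = rt.roc_from_samples([3, 5, 7], [1, 2, 4], direction="controls_lower")
        c2 = rt.roc_from_samples([3, 5, 7], [1, 2, 4], direction="controls_higher")
        with pytest.raises(InvalidInputError):
            rt.delong_test(c1, c2, paired=True)

    def test_paired_beats_unpaired_under_correlation(self):
        # strongly correlated markers with a small AUC shift: accounting for
        # the pairing should yield the smaller p-value nearly always
        rng = np.random.default_rng(11)
        wins = 0
        trials = 100
        for _ in range(trials):
            seed = int(rng.integers(2**31))
            spec = rt.BinormalSpec(mu_case=1.0, mu_case2=1.35, n_case=40,
                                   n_control=40, rho=0.9, seed=seed)
            s = rt.binormal_sample(spec, paired=True)
            c1 = rt.build_roc(s.response, s.marker1, positive_label=1,
                              direction="controls_lower")
            c2 = rt.build_roc(s.response, s.marker2, positive_label=1,
                              direction="controls_lower")
            p_paired = rt.delong_test(c1, c2, paired=True).p_value
            p_unpaired = rt.delong_test(c1, c2, paired=False).p_value
            wins += p_paired < p_unpaired
        assert wins / trials >= 0.9


class TestBootstrap:
    def test_identical_markers_degenerate(self, toy_curve):
        plan = rt.ResamplePlan(n_replicates=20, seed=0, paired=True)
        res = rt.bootstrap_test(toy_curve, toy_curve, plan=plan)
        assert res.degenerate and res.p_value == 1.0

    def test_seed_reproducibility(self, paired_cohort):
        _, c1, c2 = paired_cohort
        r1 = rt.bootstrap_test(c1, c2, plan=rt.ResamplePlan(100, seed=7, paired=True))
        r2 = rt.bootstrap_test(c1, c2, plan=rt.ResamplePlan(100, seed=7, paired=True))
        assert r1.statistic == r2.statistic and r1.p_value == r2.p_value

    def test_pauc_metric_and_standardized(self, paired_cohort):
        _, c1, c2 = paired_cohort
        pr = rt.PartialRange(0.9, 1.0)
        plan = rt.ResamplePlan(200, seed=3, paired=True)
        res = rt.bootstrap_test(c1, c2, metric="pauc", prange=pr, plan=plan)
        assert 0 <= res.p_value <= 1
        e1, e2 = res.estimates
        assert e1 == pytest.approx(float(c1.partial_auc(pr)))
        assert e2 == pytest.approx(float(c2.partial_auc(pr)))

    def test_smoothed_auc_metric_all_methods(self, paired_cohort):
        _, c1, c2 = paired_cohort
        for method in ("binormal", "density", "distribution_fit"):
            plan = rt.ResamplePlan(30, seed=4, paired=True)
            res = rt.bootstrap_test(c1, c2, metric="smoothed_auc", plan=plan,
                                    smooth_method=method)
            assert 0 <= res.p_value <= 1

    def test_agrees_with_delong_on_same_data(self, paired_cohort):
        _, c1, c2 = paired_cohort
        pd = rt.delong_test(c1, c2, paired=True).p_value
        pb = rt.bootstrap_test(
            c1, c2, plan=rt.ResamplePlan(2000, seed=8, paired=True)
        ).p_value
        assert abs(pd - pb) < 0.1


class TestVenkatraman:
    def test_identical_markers_zero_statistic(self):
        resp = [0, 0, 0, 1, 1, 1]
        m = [1.0, 2.0, 4.0, 3.0, 5.0, 7.0]
        res = rt.venkatraman_test(m, m, resp, paired=True, n_permutations=50, seed=0)
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_statistic_invariant_to_monotone_transforms(self):
        rng = np.random.default_rng(9)
        resp = np.r_[np.ones(15, int), np.zeros(20, int)]
        m1 = np.r_[rng.normal(1, 1, 15), rng.normal(0, 1, 20)]
        m2 = np.r_[rng.normal(1, 1, 15), rng.normal(0, 1, 20)]
        base = rt.venkatraman_test(m1, m2, resp, paired=True,
                                   n_permutations=100, seed=4)
        warped = rt.venkatraman_test(np.exp(m1), m2**3 + 2 * m2, resp,
                                     paired=True, n_permutations=100, seed=4)
        assert warped.statistic == base.statistic
        assert warped.p_value == base.p_value

    def test_error_curve_by_direct_counting(self):
        # 2 cases (ranks 3, 4) and 2 controls (ranks 1, 2): cut-off k
        # misclassifies every case with rank <= k and control with rank > k
        ranks = np.array([1.0, 2.0, 3.0, 4.0])
        is_case = np.array([False, False, True, True])
        np.testing.assert_array_equal(
            _error_curve_midrank(ranks, is_case), [1, 0, 1]
        )

    def test_exhaustive_enumeration_matches_naive_oracle(self):
        # small paired design: the vectorised permutation machinery must
        # reproduce a naive re-implementation over all 2^n swap patterns
        rng = np.random.default_rng(21)
        n = 6
        resp = np.array([1, 1, 1, 0, 0, 0])
        m1 = rng.normal(size=n) + resp
        m2 = rng.normal(size=n) + resp
        res = rt.venkatraman_test(m1, m2, resp, paired=True, seed=17,
                                  exhaustive=True, direction="controls_lower")
        # naive oracle: same seeded draws, independent computation
        r_x, r_y = stats.rankdata(m1), stats.rankdata(m2)
        is_case = resp == 1
        oracle_rng = np.random.default_rng(17)
        b = 2**n
        patterns = ((np.arange(b)[:, None] >> np.arange(n)[None, :]) & 1).astype(bool)
        u_x = oracle_rng.random((b, n))
        u_y = oracle_rng.random((b, n))
        null = []
        for pat, ux, uy in zip(patterns, u_x, u_y):
            rx = [ry_ if s else rx_ for rx_, ry_, s in zip(r_x, r_y, pat)]
            ry = [rx_ if s else ry_ for rx_, ry_, s in zip(r_x, r_y, pat)]
            kx = sorted(range(n), key=lambda i: rx[i] + 0.5 * ux[i])
            ky = sorted(range(n), key=lambda i: ry[i] + 0.5 * uy[i])
            e = 0
            cum_x = cum_y = 0
            for k in range(n - 1):
                cum_x += is_case[kx[k]]
                cum_y += is_case[ky[k]]
                e += 2 * abs(int(cum_x) - int(cum_y))
            null.append(e)
        e_obs = float(np.sum(np.abs(_error_curve_midrank(r_x, is_case)
                                    - _error_curve_midrank(r_y, is_case))))
        assert res.statistic == e_obs
        assert res.p_value == np.mean(np.asarray(null) >= e_obs)

    def test_unpaired_basic_and_validation(self):
        rng = np.random.default_rng(3)
        resp1 = np.r_[np.ones(10, int), np.zeros(12, int)]
        resp2 = np.r_[np.ones(9, int), np.zeros(14, int)]
        m1 = np.r_[rng.normal(1, 1, 10), rng.normal(0, 1, 12)]
        m2 = np.r_[rng.normal(1, 1, 9), rng.normal(0, 1, 14)]
        res = rt.venkatraman_test(m1, m2, resp1, paired=False, response2=resp2,
                                  n_permutations=100, seed=6)
        assert 0 <= res.p_value <= 1 and res.statistic >= 0
        with pytest.raises(InvalidInputError):
            rt.venkatraman_test(m1, m2, resp1, paired=False, n_permutations=10)

    def test_constant_markers_trivial(self):
        resp = [0, 0, 1, 1]
        m = [2.0, 2.0, 2.0, 2.0]
        res = rt.venkatraman_test(m, m, resp, paired=True, n_permutations=20, seed=1)
        assert res.statistic == 0.0 and res.p_value == 1.0


class TestFixedPoint:
    def test_identical_markers_degenerate(self, toy_curve):
        plan = rt.ResamplePlan(20, seed=2, paired=True)
        res = rt.fixed_point_test(toy_curve, toy_curve, 0.9, plan=plan)
        assert res.degenerate and res.p_value == 1.0

    def test_strong_separation_highly_significant(self):
        rng = np.random.default_rng(14)
        good = rt.roc_from_samples(rng.normal(4, 1, 80), rng.normal(0, 1, 80),
                                   direction="controls_lower")
        null = rt.roc_from_samples(rng.normal(0, 1, 80), rng.normal(0, 1, 80),
                                   direction="controls_lower")
        res = rt.fixed_point_test(good, null, 0.9, plan=rt.ResamplePlan(200, seed=5))
        assert res.p_value < 1e-4
        assert res.estimates[0] - res.estimates[1] > 0.5

    def test_close_to_narrow_pauc_test(self):
        # the fixed-point test is a pAUC test over a vanishing window
        rng = np.random.default_rng(30)
        diffs = []
        for _ in range(10):
            seed = int(rng.integers(2**31))
            s = rt.null_pair_sample(rt.BinormalSpec(mu_case=1.0, n_case=40,
                                                    n_control=40, rho=0.5,
                                                    seed=seed))
            c1 = rt.build_roc(s.response, s.marker1, positive_label=1,
                              direction="controls_lower")
            c2 = rt.build_roc(s.response, s.marker2, positive_label=1,
                              direction="controls_lower")
            plan = rt.ResamplePlan(400, seed=seed, paired=True)
            p_fix = rt.fixed_point_test(c1, c2, 0.8, plan=plan).p_value
            pr = rt.PartialRange(0.795, 0.805)
            p_pauc = rt.bootstrap_test(
                c1, c2, metric="pauc", prange=pr,
                plan=rt.ResamplePlan(400, seed=seed, paired=True),
            ).p_value
            diffs.append(abs(p_fix - p_pauc))
        assert np.median(diffs) < 0.1

    def test_boundary_points_rejected(self, toy_curve):
        with pytest.raises(InvalidInputError):
            rt.fixed_point_test(toy_curve, toy_curve, 1.0)


class TestArePaired:
    def test_same_response_is_paired(self):
        resp = [0, 0, 1, 1]
        c1 = rt.build_roc(resp, [1.0, 2.0, 3.0, 4.0], positive_label=1)
        c2 = rt.build_roc(resp, [4.0, 3.0, 2.0, 1.0], positive_label=1)
        assert rt.are_paired(c1, c2)

    def test_length_or_label_mismatch_not_paired(self):
        c1 = rt.build_roc([0, 0, 1, 1], [1.0, 2.0, 3.0, 4.0], positive_label=1)
        c2 = rt.build_roc([0, 1, 1], [1.0, 2.0, 3.0], positive_label=1)
        c3 = rt.build_roc([0, 1, 0, 1], [1.0, 2.0, 3.0, 4.0], positive_label=1)
        assert not rt.are_paired(c1, c2)
        assert not rt.are_paired(c1, c3)

    def test_sample_built_curves_are_not_paired(self, toy_curve):
        assert not rt.are_paired(toy_curve, toy_curve)
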