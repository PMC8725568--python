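"""Marker tests, global heterogeneity tests, BH-FDR and meta-analysis."""

from types import SimpleNamespace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats

from tumorhet import (
    bh_fdr,
    build_model,
    global_test_fixed,
    global_test_mixed,
    marker_tests,
    meta_fixed,
    meta_global_mixed,
    mixture_chisq_sf,
)
from tumorhet.heterogeneity import _null_score_pieces, stratum_score_pieces

from conftest import make_cohort


def wald_stub(theta, cov, labels=("baseline", "ER", "PR", "HER2", "grade")):
    """Minimal object exposing the attributes global_test_fixed reads."""
    theta = np.asarray(theta, float)
    return SimpleNamespace(
        model=SimpleNamespace(design=SimpleNamespace(kind="main_effects")),
        theta=theta, cov_theta=np.asarray(cov, float),
        theta_labels=labels, converged=True,
        theta_table=None)


class TestMarkerTests:
    def test_wald_z_and_p(self, mar_cohort):
        data, _ = mar_cohort
        fit = build_model(data, "v").fit()
        tab = marker_tests(fit)
        assert list(tab.index) == ["ER", "PR", "HER2", "grade"]
        # independent normal-CDF oracle by quadrature
        for _, row in tab.iterrows():
            tail, _ = integrate.quad(
                lambda t: np.exp(-t * t / 2) / np.sqrt(2 * np.pi),
                abs(row["z"]), 40)
            assert row["p"] == pytest.approx(2 * tail, abs=1e-10)

    def test_nonconverged_fit_rejected(self, mar_cohort):
        data, _ = mar_cohort
        fit = build_model(data, "v").fit()
        fit.converged = False
        with pytest.raises(ValueError, match="converge"):
            marker_tests(fit)

    def test_z_arithmetic(self):
        # theta/se = 2 -> two-sided normal p ~ 0.0455
        assert 2 * stats.norm.sf(2.0) == pytest.approx(0.0455, abs=2e-4)


class TestGlobalFixed:
    def test_zero_theta_gives_p_one(self):
        res = global_test_fixed(wald_stub([0.3, 0, 0, 0, 0], np.eye(5)))
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_unit_statistic_chisq4(self):
        res = global_test_fixed(wald_stub([0, 1, 0, 0, 0], np.eye(5)))
        assert res.statistic == pytest.approx(1.0)
        assert res.p_value == pytest.approx(0.9098, abs=2e-4)
        assert res.p_value == pytest.approx(stats.chi2.sf(1.0, 4), abs=1e-12)

    def test_invariant_to_marker_reordering(self):
        rng = np.random.default_rng(0)
        L = rng.standard_normal((5, 5))
        cov = L @ L.T + np.eye(5)
        th = rng.standard_normal(5) * 0.1
        base = global_test_fixed(wald_stub(th, cov)).statistic
        perm = [0, 3, 1, 4, 2]  # keep baseline first
        labels = tuple(np.array(["baseline", "ER", "PR", "HER2", "grade"])[perm])
        got = global_test_fixed(
            wald_stub(th[perm], cov[np.ix_(perm, perm)], labels)).statistic
        assert got == pytest.approx(base, rel=1e-12)


class TestMixtureChisq:
    def test_equal_weights_match_chisq(self):
        for q in (0.5, 3.0, 9.49, 20.0):
            assert mixture_chisq_sf(q, np.ones(4)) == pytest.approx(
                stats.chi2.sf(q, 4), abs=1e-7)

    def test_single_weight_scales_chisq1(self):
        assert mixture_chisq_sf(5.0, np.array([2.5])) == pytest.approx(
            stats.chi2.sf(2.0, 1), abs=1e-12)

    def test_nonpositive_q_gives_one(self):
        assert mixture_chisq_sf(0.0, np.ones(3)) == 1.0


class TestGlobalMixed:
    def test_mixture_and_monte_carlo_agree(self):
        diffs = []
        for seed in range(40, 60):
            data, _ = make_cohort(
                n_cases=500, n_controls=500, seed=seed,
                theta=[0.1, 0.1, 0, 0, 0],
                missing_rates={"PR": 0.3, "HER2": 0.4, "grade": 0.3})
            r1 = global_test_mixed(data, "v", method="mixture_chisq")
            r2 = global_test_mixed(data, "v", method="monte_carlo",
                                   n_draws=200_000, seed=seed)
            diffs.append(abs(r1.p_value - r2.p_value))
        assert max(diffs) < 0.005

    def test_constant_dosage_rejected(self):
        data, _ = make_cohort(n_cases=100, n_controls=100, seed=61)
        data.dosages[0] = 2.0
        with pytest.raises(ValueError, match="no genotype variation"):
            global_test_mixed(data, "v")

    def test_statistic_has_fixed_and_random_parts(self, mar_cohort):
        data, _ = mar_cohort
        res = global_test_mixed(data, "v")
        fixed, random = res.components
        assert fixed >= 0 and random >= 0
        assert res.statistic == pytest.approx(fixed + random, rel=1e-10)
        assert 0 <= res.p_value <= 1

    def test_power_exceeds_alpha_under_er_heterogeneity(self):
        # strict improvement over the nominal level, not a power claim:
        # 7+/60 rejections has probability ~0.03 under a calibrated null
        rej_f = rej_m = 0
        n_rep = 60
        for seed in range(300, 300 + n_rep):
            data, _ = make_cohort(n_cases=2500, n_controls=2500, seed=seed,
                                  theta=[0.0, 0.15, 0, 0, 0])
            fit = build_model(data, "v").fit()
            rej_f += global_test_fixed(fit).p_value < 0.05
            rej_m += global_test_mixed(data, "v").p_value < 0.05
        assert rej_f >= 7
        assert rej_m >= 7


class TestMetaGlobalMixed:
    def test_single_stratum_identity(self, mar_cohort):
        data, _ = mar_cohort
        res1 = global_test_mixed(data, "v")
        pieces = [_null_score_pieces(data, "v")]
        res2 = meta_global_mixed(pieces)
        assert res2.statistic == pytest.approx(res1.statistic, rel=1e-10)
        assert res2.p_value == pytest.approx(res1.p_value, abs=1e-8)

    def test_duplicated_stratum_doubles_statistic(self, mar_cohort):
        data, _ = mar_cohort
        piece = _null_score_pieces(data, "v")
        one = meta_global_mixed([piece])
        two = meta_global_mixed([piece, piece])
        assert two.statistic == pytest.approx(2 * one.statistic, rel=1e-10)

    def test_mismatched_parameterizations_rejected(self, mar_cohort):
        data, _ = mar_cohort
        U, V, labels = _null_score_pieces(data, "v")
        with pytest.raises(ValueError, match="mismatched"):
            meta_global_mixed([(U, V, labels), (U, V, ["a", "b", "c", "d"])])

    def test_two_stratum_null_calibration(self):
        # unequal strata under H0: rejection close to the nominal level
        rej = 0
        n_rep = 60
        for seed in range(400, 400 + n_rep):
            data, _ = make_cohort(
                theta=[0.1, 0, 0, 0, 0], seed=seed,
                strata={"a": (1500, 1200), "b": (700, 900)},
                missing_rates={"PR": 0.27, "HER2": 0.46, "grade": 0.27})
            pieces = stratum_score_pieces(data, "v")
            rej += meta_global_mixed(pieces).p_value < 0.05
        lo, hi = stats.binom.ppf([0.005, 0.995], n_rep, 0.05)
        assert lo <= rej <= hi


class TestBHFDR:
    def test_hand_example(self):
        q = bh_fdr([0.01, 0.02, 0.04, 0.5])
        assert np.allclose(q, [0.04, 0.04, 0.04 * 4 / 3, 0.5])

    def test_single_p_unchanged(self):
        assert bh_fdr([0.137])[0] == pytest.approx(0.137)

    def test_ties_all_equal(self):
        assert np.allclose(bh_fdr([0.2] * 5), 0.2)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1,
                    max_size=40))
    @settings(max_examples=200, deadline=None)
    def test_matches_step_up_oracle(self, pvals):
        q = bh_fdr(pvals)
        # independent closed-form step-up: q_(i) = min_{j>=i} p_(j) m / j
        p = np.asarray(pvals, float)
        m = len(p)
        order = np.argsort(p, kind="mergesort")
        ranked = p[order] * m / np.arange(1, m + 1)
        q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
        oracle = np.empty(m)
        oracle[order] = np.minimum(q_sorted, 1.0)
        assert np.allclose(q, oracle, atol=1e-12)
        assert np.all(q >= p - 1e-12)


class TestMetaFixed:
    def test_scalar_hand_arithmetic(self):
        th, cov = meta_fixed([(0.2, 0.01), (0.4, 0.04)])
        assert th[0] == pytest.approx(0.24, abs=1e-12)
        assert cov[0, 0] == pytest.approx(0.008, abs=1e-12)

    def test_identical_strata_halve_variance(self):
        rng = np.random.default_rng(1)
        L = rng.standard_normal((4, 4))
        cov = L @ L.T + 4 * np.eye(4)
        th = rng.standard_normal(4)
        mth, mcov = meta_fixed([(th, cov), (th, cov)])
        assert np.allclose(mth, th, atol=1e-12)
        assert np.allclose(mcov, cov / 2, atol=1e-12)

    def test_single_stratum_identity(self):
        th, cov = meta_fixed([(np.array([0.1, 0.2]), np.eye(2) * 0.3)])
        assert np.allclose(th, [0.1, 0.2])
        assert np.allclose(cov, np.eye(2) * 0.3)

    def test_vector_case_matches_direct_linear_algebra(self):
        rng = np.random.default_rng(2)
        ests = []
        for _ in range(3):
            L = rng.standard_normal((3, 3))
            ests.append((rng.standard_normal(3), L @ L.T + 2 * np.eye(3)))
        th, cov = meta_fixed(ests)
        precs = [np.linalg.inv(c) for _, c in ests]
        cov_o = np.linalg.inv(np.sum(precs, axis=0))
        th_o = cov_o @ np.sum([P @ t for (t, _), P in zip(ests, precs)], axis=0)
        assert np.allclose(th, th_o, atol=1e-12)
        assert np.allclose(cov, cov_o, atol=1e-12)

    def test_nonconformable_rejected(self):
        with pytest.raises(ValueError, match="conformable"):
            meta_fixed([(np.zeros(2), np.eye(2)), (np.zeros(3), np.eye(3))])
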