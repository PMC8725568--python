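"""Two-stage likelihood, EM/Newton fitting and complete-case comparison."""

import json

import numpy as np
import pytest

from tumorhet import (
    CohortData,
    ConvergenceError,
    MarkerSchema,
    ObservedPattern,
    SecondStageDesign,
    build_model,
    estep_weights,
    fit_complete_case_polytomous,
)
from tumorhet.markers import consistent_intrinsic

from conftest import make_cohort

TOY = MarkerSchema(markers=(("ER", ("neg", "pos")),))


def toy_cohort():
    """Controls 100 g=0 / 100 g=1; cell A (ER-) cases 50/100; cell B 50/50."""
    status = np.array([0] * 200 + [1] * 250)
    g = np.array([0] * 100 + [1] * 100 + [0] * 50 + [1] * 100
                 + [0] * 50 + [1] * 50, dtype=float)
    pats = ([ObservedPattern((None,))] * 200
            + [ObservedPattern(("neg",))] * 150
            + [ObservedPattern(("pos",))] * 100)
    return CohortData(status=status, patterns=pats,
                      covariates=np.zeros((450, 0)), stratum=np.zeros(450),
                      dosages=g[None, :], variant_ids=["v"], schema=TOY)


class TestLikelihood:
    def test_uniform_params_give_uniform_categories(self):
        status = np.array([0, 1])
        pats = [ObservedPattern((None,) * 4)] * 2  # all 24 cells active
        data = CohortData(status=status, patterns=pats,
                          covariates=np.zeros((2, 0)), stratum=np.zeros(2),
                          dosages=np.array([[0.0, 1.0]]), variant_ids=["v"])
        m = build_model(data, "v")
        vec = np.zeros(m.nparams)
        # a control's probability of the control category is 1/25
        eta = m.linpred(vec)
        P, logD = m._probs(eta)
        assert np.allclose(np.exp(-logD), 1.0 / 25.0)
        assert np.allclose(P, 1.0 / 25.0)
        assert np.allclose(P.sum(axis=1) + np.exp(-logD), 1.0, atol=1e-12)

    def test_single_control_loglik(self):
        status = np.array([0, 1])
        pats = [ObservedPattern((None,) * 4), ObservedPattern((None,) * 4)]
        data = CohortData(status=status, patterns=pats,
                          covariates=np.zeros((2, 0)), stratum=np.zeros(2),
                          dosages=np.array([[0.0, 1.0]]), variant_ids=["v"])
        m = build_model(data, "v")
        # control contributes log(1/25); fully-missing case contributes
        # log(24/25)
        ll = m.loglike(np.zeros(m.nparams))
        assert ll == pytest.approx(np.log(1 / 25) + np.log(24 / 25), abs=1e-12)

    def test_genotype_term_is_linear_in_dosage(self):
        data = make_cohort(n_cases=50, n_controls=50, seed=2)[0]
        m = build_model(data, "v")
        vec = np.zeros(m.nparams)
        vec[m.Ma: m.Ma + 5] = [0.1, 0.2, -0.1, 0.05, 0.03]
        eta1 = m.linpred(vec)
        m2 = build_model(data, "v")
        m2.g = 2 * m.g.copy()
        # dosage doubled -> genotype contribution doubled
        assert np.allclose(m2.linpred(vec), 2 * eta1)

    def test_loglik_invariant_to_subject_permutation(self):
        data = make_cohort(n_cases=200, n_controls=200, seed=3,
                           missing_rates={"PR": 0.4})[0]
        m = build_model(data, "v")
        vec = m._start()
        rng = np.random.default_rng(0)
        perm = rng.permutation(data.n)
        data2 = CohortData(status=data.status[perm],
                           patterns=[data.patterns[i] for i in perm],
                           covariates=data.covariates[perm],
                           stratum=data.stratum[perm],
                           dosages=data.dosages[:, perm],
                           variant_ids=["v"])
        m2 = build_model(data2, "v")
        assert m2.loglike(vec) == pytest.approx(m.loglike(vec), rel=1e-12)


class TestEStep:
    def test_uniform_params_spread_weight_evenly(self):
        status = np.array([0, 1, 1])
        pats = [ObservedPattern((None,) * 4), ObservedPattern((None,) * 4),
                ObservedPattern(("pos", None, None, None))]
        data = CohortData(status=status, patterns=pats,
                          covariates=np.zeros((3, 0)), stratum=np.zeros(3),
                          dosages=np.array([[0.0, 1.0, 2.0]]),
                          variant_ids=["v"])
        m = build_model(data, "v")
        W = estep_weights(m, np.zeros(m.nparams))
        case_w = W[2][W[2] > 0]
        assert len(case_w) == 12
        assert np.allclose(case_w, 1 / 12)

    def test_fully_observed_case_gets_unit_weight(self, complete_cohort):
        data, _ = complete_cohort
        m = build_model(data, "v")
        W = estep_weights(m, m._start())
        cases = data.status == 1
        assert np.allclose(W[cases].max(axis=1), 1.0)
        assert np.allclose(W[cases].sum(axis=1), 1.0)

    def test_weights_match_bruteforce_posterior(self):
        rng = np.random.default_rng(5)
        data = make_cohort(n_cases=50, n_controls=50, seed=6,
                           missing_rates={"HER2": 0.5, "grade": 0.5})[0]
        m = build_model(data, "v")
        vec = m._start() + 0.1 * rng.standard_normal(m.nparams)
        W = estep_weights(m, vec)
        eta = m.linpred(vec)
        for i in np.flatnonzero(data.status == 1)[:10]:
            idx = np.flatnonzero(m.mask[i])
            post = np.exp(eta[i, idx])
            post /= post.sum()
            assert np.allclose(W[i, idx], post, atol=1e-12)


class TestFit:
    def test_toy_saturated_closed_form(self):
        res = build_model(toy_cohort(), "v", design_kind="saturated").fit()
        assert res.theta == pytest.approx([np.log(2), 0.0], abs=1e-6)

    def test_toy_reparametrized_design(self):
        A = np.array([[1.0, 0.0], [1.0, 1.0]])
        d = SecondStageDesign(kind="custom", matrix=A, labels=("t0", "t1"))
        res = build_model(toy_cohort(), "v", design=d).fit()
        assert res.theta == pytest.approx([np.log(2), -np.log(2)], abs=1e-6)

    def test_null_simulation_covers_zero(self):
        data, _ = make_cohort(n_cases=1000, n_controls=1000, seed=7)
        res = build_model(data, "v").fit()
        assert np.all(np.abs(res.theta[1:]) <= 3 * res.bse_theta[1:])

    def test_score_is_zero_at_optimum(self, mar_cohort):
        data, _ = mar_cohort
        m = build_model(data, "v")
        res = m.fit()
        assert res.converged
        assert np.abs(m.score(res.params_vec)).max() < 1e-5

    @pytest.mark.parametrize("seed", [11, 12, 13])
    def test_em_and_newton_agree(self, seed):
        data, _ = make_cohort(
            n_cases=1000, n_controls=1000, seed=seed,
            theta=[0.1, 0.15, 0, 0, 0],
            missing_rates={"PR": 0.3, "HER2": 0.4, "grade": 0.3})
        m = build_model(data, "v")
        r_new = m.fit(method="newton")
        r_em = m.fit(method="em")
        assert np.abs(r_new.theta - r_em.theta).max() < 1e-5

    def test_em_loglik_monotone(self):
        for seed in range(20, 25):
            data, _ = make_cohort(
                n_cases=600, n_controls=600, seed=seed,
                missing_rates={"ER": 0.2, "PR": 0.3, "HER2": 0.4, "grade": 0.3})
            m = build_model(data, "v")
            res = m.fit(method="em")
            diffs = np.diff(res.loglik_trace)
            assert (diffs >= -1e-10).all()

    def test_separation_raises(self):
        status = np.array([0] * 100 + [1] * 100)
        g = np.concatenate([np.tile([0.0, 1.0], 50), np.full(50, 2.0),
                            np.tile([0.0, 1.0], 25)])
        pats = ([ObservedPattern((None,))] * 100
                + [ObservedPattern(("pos",))] * 50
                + [ObservedPattern(("neg",))] * 50)
        data = CohortData(status=status, patterns=pats,
                          covariates=np.zeros((200, 0)),
                          stratum=np.zeros(200), dosages=g[None, :],
                          variant_ids=["v"], schema=TOY)
        with pytest.raises(ConvergenceError, match="separation"):
            build_model(data, "v", design_kind="saturated").fit()

    def test_constant_dosage_rejected(self):
        data, _ = make_cohort(n_cases=20, n_controls=20, seed=8)
        data.dosages[0] = 1.0
        with pytest.raises(ValueError, match="no genotype variation"):
            build_model(data, "v")

    def test_results_serialization_roundtrip(self, complete_cohort, tmp_path):
        data, _ = complete_cohort
        res = build_model(data, "v").fit()
        path = tmp_path / "fit.json"
        res.to_json(path)
        obj = json.loads(path.read_text())
        assert obj["converged"]
        assert np.allclose(obj["theta"], res.theta)
        assert np.allclose(obj["cov_theta"], res.cov_theta)
        assert obj["design"] == "main_effects"


class TestCompleteCase:
    def test_no_missingness_equals_em_on_cells(self):
        data, _ = make_cohort(theta=[0.1, 0.1, -0.05, 0.05, 0.03],
                              seed=101, flat=True)
        res_cc, ndrop = fit_complete_case_polytomous(data, "v",
                                                     categories="cells")
        assert ndrop == 0
        res_em = build_model(data, "v", design_kind="saturated").fit(method="em")
        em = {lab.removeprefix("cell_"): th
              for lab, th in zip(res_em.theta_labels, res_em.theta)}
        cc = dict(zip(res_cc.theta_labels, res_cc.theta))
        shared = set(em) & set(cc)
        assert len(shared) >= 20
        for lab in shared:
            assert cc[lab] == pytest.approx(em[lab], abs=1e-5)

    def test_dropped_count_equals_ambiguous_cases(self, mar_cohort):
        data, _ = mar_cohort
        _, ndrop = fit_complete_case_polytomous(data, "v",
                                                categories="intrinsic5")
        expected = sum(
            1 for i in range(data.n) if data.status[i] == 1
            and len(consistent_intrinsic(data.patterns[i])) > 1)
        assert ndrop == expected

    def test_missingness_costs_precision(self):
        # EM uses partial patterns the complete-case analysis drops
        worse = total = 0
        for seed in (31, 32, 33):
            data, _ = make_cohort(
                n_cases=2500, n_controls=2500, seed=seed,
                theta=[0.1, 0.1, 0, 0, 0],
                missing_rates={"ER": 0.19, "PR": 0.27, "HER2": 0.46,
                               "grade": 0.27})
            from tumorhet import fit_model3
            tab, _ = fit_model3(data, "v", return_results=True)
            res_cc, _ = fit_complete_case_polytomous(data, "v",
                                                     categories="intrinsic5")
            cc = res_cc.or_table()
            for lab in tab.index:
                if lab in cc.index and np.isfinite(tab.loc[lab, "se"]):
                    total += 1
                    worse += cc.loc[lab, "se"] >= tab.loc[lab, "se"]
        assert worse / total >= 0.8
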