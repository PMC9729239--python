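"""Multivariable MR: design-matrix construction, rank-score pooling,
direct-effect estimation, conditional F and MVMR heterogeneity."""

import numpy as np
import pytest

from mrmediate.ivw import IVWModel
from mrmediate.mvmr import (MVMRModel, MVMRProblem, UntestablePairError,
                            build_design_matrix, conditional_f,
                            rank_score_clump)

from conftest import make_panel, make_table


def mvmr_gls_oracle(B, bY, C):
    """Explicit normal-equation solve, independent of the model code."""
    Ci = np.linalg.inv(C)
    return np.linalg.solve(B.T @ Ci @ B, B.T @ Ci @ bY)


def random_corr(rng, m):
    A = rng.normal(size=(m, m + 5))
    S = A @ A.T + m * np.eye(m)
    d = np.sqrt(np.diag(S))
    return S / np.outer(d, d)


def make_problem(B, bY, C=None, var=1e-4):
    B = np.asarray(B, float)
    m, ncol = B.shape
    C = np.eye(m) if C is None else C
    return MVMRProblem("p", [f"iv{i}" for i in range(m)], B, bY,
                       np.full(m, var), C,
                       mediator_ids=[f"M{j}" for j in range(ncol - 1)])


class TestEstimate:
    def test_no_mediators_reduces_to_ivw(self, rng):
        bE, bY = rng.normal(size=5), rng.normal(size=5)
        C = random_corr(rng, 5)
        mv = MVMRModel(make_problem(bE[:, None], bY, C)).fit()
        uni = IVWModel.from_arrays(bE, np.full(5, 1e-4), bY,
                                   np.full(5, 1e-4), C).fit()
        assert mv.theta_D == pytest.approx(uni.theta, abs=1e-12)

    def test_noiseless_full_mediation_chain(self, rng):
        # beta_Y = a_EM*a_MY*beta_E on exposure IVs, a_MY*beta_dir on
        # mediator IVs: theta_D = 0, alpha_MY recovered exactly
        a_em, a_my = 0.5, 0.3
        bE = np.array([0.2, 0.25, 0.3, 0.0, 0.0])
        b_dir = np.array([0.0, 0.0, 0.0, 0.4, 0.35])
        bM = a_em * bE + b_dir
        bY = a_my * bM
        mv = MVMRModel(make_problem(np.column_stack([bE, bM]), bY)).fit()
        assert mv.theta_D == pytest.approx(0.0, abs=1e-12)
        assert mv.alpha_MY["M0"][0] == pytest.approx(a_my, abs=1e-12)

    def test_matches_gls_oracle_with_mediators(self, rng):
        for _ in range(20):
            m = int(rng.integers(4, 10))
            k = int(rng.integers(1, min(3, m - 3) + 1))
            B = rng.normal(size=(m, k + 1))
            bY = rng.normal(size=m)
            C = random_corr(rng, m)
            mv = MVMRModel(make_problem(B, bY, C)).fit()
            expect = mvmr_gls_oracle(B, bY, C)
            assert mv.theta_vec == pytest.approx(expect, abs=1e-10)

    def test_identity_ld_equals_ordinary_least_squares(self, rng):
        B = rng.normal(size=(8, 3))
        bY = rng.normal(size=8)
        mv = MVMRModel(make_problem(B, bY)).fit()
        ols, *_ = np.linalg.lstsq(B, bY, rcond=None)
        assert mv.theta_vec == pytest.approx(ols, abs=1e-10)

    def test_zero_effect_mediator_leaves_theta_unchanged(self, rng):
        bE, bY = rng.normal(size=6), rng.normal(size=6)
        base = MVMRModel(make_problem(bE[:, None], bY)).fit()
        B2 = np.column_stack([bE, np.zeros(6)])
        aug = MVMRModel(make_problem(B2, bY)).fit()
        assert aug.theta_D == pytest.approx(base.theta_D, abs=1e-10)
        assert aug.dropped_mediators == ["M0"]

    def test_collinear_mediator_dropped_and_recorded(self, rng):
        bE, bY = rng.normal(size=6), rng.normal(size=6)
        bM = rng.normal(size=6)
        B = np.column_stack([bE, bM, 2 * bM])
        mv = MVMRModel(make_problem(B, bY)).fit()
        assert mv.dropped_mediators == ["M1"]
        assert mv.k == 1

    def test_too_few_exposure_ivs_untestable(self, rng):
        B = np.column_stack([[0.3, 0.2, 0.0, 0.0],
                             [0.1, 0.05, 0.4, 0.3]])
        with pytest.raises(UntestablePairError):
            MVMRModel(make_problem(B, rng.normal(size=4)))

    def test_difference_equals_product_method_in_exact_model(self):
        # theta_T - theta_D == alpha_EM * alpha_MY exactly without noise
        a_em, a_my, theta_d = -0.4, 0.25, 0.05
        bE = np.array([0.2, 0.3, 0.25, 0.0, 0.0, 0.0])
        b_dir = np.array([0.0, 0.0, 0.0, 0.35, 0.3, 0.4])
        bM = a_em * bE + b_dir
        bY = theta_d * bE + a_my * bM
        mv = MVMRModel(make_problem(np.column_stack([bE, bM]), bY)).fit()
        uni = IVWModel.from_arrays(bE[:3], np.full(3, 1e-4), bY[:3],
                                   np.full(3, 1e-4)).fit()
        assert mv.theta_D == pytest.approx(theta_d, abs=1e-12)
        assert uni.theta - mv.theta_D == pytest.approx(a_em * a_my,
                                                       abs=1e-12)


class TestRankScoreClump:
    def _stats(self, trait, rows):
        return make_table(trait, "mediator", rows)

    def test_single_mediator_order_is_pvalue_order(self):
        tab = self._stats("m1", [("a", 1, 1000, "A", "G", .3, .4, .01),
                                 ("b", 1, 2000, "A", "G", .3, .3, .01)])
        panel = make_panel(["a", "b"], np.eye(2))
        pooled = rank_score_clump([], {"m1": tab}, panel)
        assert pooled == ["a", "b"]   # |z| 40 > 30

    def test_two_mediator_rank_sum(self):
        # IV a ranks (1, 3) -> 4; IV b ranks (2, 1) -> 3; b precedes a
        m1 = self._stats("m1", [("a", 1, 1000, "A", "G", .3, .50, .01),
                                ("b", 1, 2000, "A", "G", .3, .40, .01),
                                ("c", 1, 3000, "A", "G", .3, .30, .01)])
        m2 = self._stats("m2", [("a", 1, 1000, "A", "G", .3, .20, .01),
                                ("b", 1, 2000, "A", "G", .3, .45, .01),
                                ("c", 1, 3000, "A", "G", .3, .35, .01)])
        panel = make_panel(["a", "b", "c"], np.eye(3))
        pooled = rank_score_clump([], {"m1": m1, "m2": m2}, panel)
        assert pooled[0] == "b" and pooled[1] == "a"

    def test_mediator_iv_clumped_against_kept_exposure_iv(self):
        tab = self._stats("m1", [("b", 1, 2000, "A", "G", .3, .4, .01)])
        r = np.sqrt(0.9)
        panel = make_panel(["a", "b"], [[1, r], [r, 1]])
        pooled = rank_score_clump(["a"], {"m1": tab}, panel)
        assert pooled == ["a"]   # r2 = 0.9 with exposure IV 'a'


class TestDesignMatrix:
    def _fixture(self):
        exp = make_table("e", "exposure",
                         [("a", 1, 1000, "A", "G", .3, 0.2, .01),
                          ("b", 1, 2000, "A", "G", .3, 0.15, .01)])
        med = make_table("m1", "mediator",
                         [("b", 1, 2000, "A", "G", .3, 0.1, .01),
                          ("c", 1, 3000, "A", "G", .3, 0.4, .01)])
        out = make_table("y", "outcome",
                         [("a", 1, 1000, "A", "G", .3, 0.05, .01),
                          ("b", 1, 2000, "A", "G", .3, 0.04, .01),
                          ("c", 1, 3000, "A", "G", .3, 0.02, .01)])
        panel = make_panel(["a", "b", "c"], np.eye(3))
        return exp, med, out, panel

    def test_reported_effects_fill_and_unreported_are_zero(self):
        exp, med, out, panel = self._fixture()
        prob = build_design_matrix(exp, {"m1": med}, out,
                                   ["a", "b", "c"], panel)
        # 'c' absent from the mQTL table -> exposure entry exactly 0
        assert prob.B[2, 0] == 0.0
        # 'a' absent from the eQTL table -> mediator entry exactly 0
        assert prob.B[0, 1] == 0.0
        assert prob.B[1, 0] == pytest.approx(0.15)
        assert prob.B[1, 1] == pytest.approx(0.1)

    def test_iv_missing_from_outcome_dropped(self):
        exp, med, out, panel = self._fixture()
        out2 = out.subset(["a", "b"])
        prob = build_design_matrix(exp, {"m1": med}, out2,
                                   ["a", "b", "c"], panel)
        assert prob.iv_ids == ["a", "b"]


class TestConditionalF:
    def test_no_mediator_reduction_to_mean_f(self, rng):
        bE = rng.normal(size=6) * 0.1
        C = random_corr(rng, 6)
        prob = make_problem(bE[:, None], np.zeros(6), C)
        n = 20_000
        expect = n * float(bE @ np.linalg.inv(C) @ bE) / 6
        assert conditional_f(prob, n) == pytest.approx(expect, rel=1e-6)

    def test_collinear_mediator_gives_zero(self):
        bE = np.array([0.2, 0.3, 0.1, 0.25])
        B = np.column_stack([bE, 2 * bE])
        prob = make_problem(B, np.zeros(4))
        assert conditional_f(prob, 10_000) == pytest.approx(0.0, abs=1e-12)

    def test_small_example_matches_manual_residual_regression(self):
        bE = np.array([0.3, 0.25, 0.2, 0.15, 0.1])
        bM = np.array([0.1, 0.2, 0.05, 0.3, 0.0])
        prob = make_problem(np.column_stack([bE, bM]), np.zeros(5))
        n_e, n_m = 30_000, 25_000
        delta = float(bM @ bE) / float(bM @ bM)
        e = bE - delta * bM
        sigma_v2 = 1 / n_e + delta ** 2 / n_m
        expect = float(e @ e) / ((5 - 1) * sigma_v2)
        assert conditional_f(prob, n_e, n_M=n_m) == pytest.approx(expect)

    def test_pheno_correlation_adjustment_changes_value(self, rng):
        B = rng.normal(size=(8, 3)) * 0.1
        prob = make_problem(B, np.zeros(8))
        base = conditional_f(prob, 10_000)
        adj = conditional_f(prob, 10_000,
                            pheno_corr=np.array([[1, .9], [.9, 1]]))
        assert adj != pytest.approx(base)

    def test_undefined_when_m_le_k(self):
        prob = make_problem(np.ones((2, 3)) * 0.1, np.zeros(2))  # m=2, k=2
        with pytest.raises(ValueError, match="undefined"):
            conditional_f(prob, 1_000)


class TestMVMRQ:
    def test_zero_on_exact_linear_model(self, rng):
        B = rng.normal(size=(7, 3))
        theta = np.array([0.1, -0.2, 0.3])
        mv = MVMRModel(make_problem(B, B @ theta)).fit()
        assert mv.q_statistic()[0] == pytest.approx(0.0, abs=1e-18)

    def test_degrees_of_freedom_m_minus_k(self, rng):
        B = rng.normal(size=(10, 4))   # k = 3
        mv = MVMRModel(make_problem(B, rng.normal(size=10))).fit()
        assert mv.q_statistic()[1] == 7

    def test_four_iv_one_mediator_brute_force(self, rng):
        B = rng.normal(size=(4, 2))
        bY = rng.normal(size=4)
        mv = MVMRModel(make_problem(B, bY)).fit()
        resid = bY - B @ mv.theta_vec
        expect = float(np.sum(resid ** 2 / mv.sigma_diag))
        assert mv.q_statistic()[0] == pytest.approx(expect)
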