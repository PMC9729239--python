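"""Mediator selection, MP regression with dilution correction, MP
comparison, product-of-coefficients and stratification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mrmediate.mediation import (MediationConfig, MediatorCandidate,
                                 MPRegression, PairResult, clump_mediators,
                                 compare_mp, estimate_mp, mediate_pair,
                                 product_of_coefficients, select_mediators,
                                 stratify_pairs)
from mrmediate.synthetic import (RegionBlueprint, TranscriptBlueprint,
                                 generate_region_fixture)


def make_pair(pair_id="p", theta_T=0.1, theta_D=0.05, se_T=0.01,
              alphas=(), detectable=None, outcome="y", **kw):
    meds = [MediatorCandidate(f"m{i}", a, 0.01, 1e-4, 5)
            for i, a in enumerate(alphas)]
    if detectable is None:
        detectable = bool(meds)
    return PairResult(pair_id, "probe", outcome, theta_T, se_T, 1e-9,
                      theta_D, 0.01, mediators=meds, detectable=detectable,
                      **kw)


class TestMPRegression:
    def test_no_dilution_when_se_zero(self, rng):
        tT = rng.normal(size=20)
        tD = 0.6 * tT + rng.normal(0, 0.01, 20)
        est = MPRegression(tT, tD, np.zeros(20)).fit()
        assert est.gamma_cor == pytest.approx(est.gamma)

    def test_identity_pairs_give_zero_mp(self, rng):
        tT = rng.normal(size=15)
        est = MPRegression(tT, tT, np.zeros(15)).fit()
        assert est.mp == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_dilution_correction(self):
        # sum SE^2 = 0.5 * sum theta_T^2 and gamma = 0.5
        # -> gamma_cor = 0.5/sqrt(0.5), MP = 1 - 0.7071 = 0.2929
        tT = np.array([1.0, 1.0])
        tD = np.array([0.5, 0.5])
        se = np.array([np.sqrt(0.5), np.sqrt(0.5)])
        est = MPRegression(tT, tD, se).fit()
        assert est.gamma == pytest.approx(0.5)
        assert est.gamma_cor == pytest.approx(0.70710678, abs=1e-6)
        assert est.mp == pytest.approx(0.29289, abs=1e-4)

    def test_correction_undefined_when_noise_dominates(self):
        with pytest.raises(ValueError, match="undefined"):
            MPRegression([0.1, 0.1], [0.05, 0.05], [0.2, 0.2]).fit()

    @given(st.integers(0, 500))
    @settings(max_examples=20, deadline=None)
    def test_invariant_to_order_and_global_sign_flip(self, seed):
        r = np.random.default_rng(seed)
        n = 12
        tT = r.normal(1, 0.3, n)
        tD = 0.5 * tT + r.normal(0, 0.05, n)
        se = np.abs(r.normal(0, 0.05, n))
        a = MPRegression(tT, tD, se).fit()
        perm = r.permutation(n)
        b = MPRegression(tT[perm], tD[perm], se[perm]).fit()
        c = MPRegression(-tT, -tD, se).fit()
        assert a.mp == pytest.approx(b.mp) == pytest.approx(c.mp)
        assert a.se_gamma_cor == pytest.approx(b.se_gamma_cor)


class TestCompareMP:
    def _est(self, gamma_cor, se=0.05):
        from mrmediate.mediation import MPEstimate
        return MPEstimate("g", 20, gamma_cor, se, gamma_cor, se)

    def test_identical_estimates_give_z_zero(self):
        z, p = compare_mp(self._est(0.6), self._est(0.6))
        assert z == 0.0 and p == pytest.approx(1.0)

    def test_difference_at_quantile_gives_p05(self):
        se = 0.05
        diff = 1.96 * np.sqrt(2) * se
        z, p = compare_mp(self._est(0.6 + diff), self._est(0.6))
        assert p == pytest.approx(0.05, abs=1e-3)

    def test_antisymmetry(self):
        a, b = self._est(0.7), self._est(0.5)
        z1, p1 = compare_mp(a, b)
        z2, p2 = compare_mp(b, a)
        assert z1 == pytest.approx(-z2) and p1 == pytest.approx(p2)

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValueError):
            compare_mp(self._est(0.6, se=0.0), self._est(0.5))


class TestProductOfCoefficients:
    def test_single_product(self):
        pair = make_pair(alphas=(0.5,))
        pair.mediators[0].alpha_MY = 0.2
        theta_M, direct = product_of_coefficients(pair)
        assert theta_M == pytest.approx(0.1)
        assert direct == pytest.approx(pair.theta_T - 0.1)

    def test_mixed_sign_sum(self):
        pair = make_pair(alphas=(0.5, -0.3, 0.2))
        for c, a_my in zip(pair.mediators, (0.2, 0.4, -0.1)):
            c.alpha_MY = a_my
        theta_M, _ = product_of_coefficients(pair)
        assert theta_M == pytest.approx(0.5 * 0.2 - 0.3 * 0.4 - 0.2 * 0.1)

    def test_missing_alpha_my_skipped_with_warning(self):
        pair = make_pair(alphas=(0.5, 0.3))
        pair.mediators[0].alpha_MY = 0.2
        with pytest.warns(UserWarning, match="no alpha_MY"):
            theta_M, _ = product_of_coefficients(pair)
        assert theta_M == pytest.approx(0.1)


class TestClumpMediators:
    def _effects(self, corr_12, corr_13, corr_23, n=40, seed=0):
        rng = np.random.default_rng(seed)
        S = np.array([[1, corr_12, corr_13],
                      [corr_12, 1, corr_23],
                      [corr_13, corr_23, 1]])
        X = rng.multivariate_normal(np.zeros(3), S, size=n)
        # force the sample correlations to the target values exactly
        X = (X - X.mean(0)) / X.std(0)
        L = np.linalg.cholesky(S)
        Q, _ = np.linalg.qr(X)
        X = Q[:, :3] @ L.T
        return pd.DataFrame(X, columns=["m0", "m1", "m2"])

    def _cands(self, pvals):
        return [MediatorCandidate(f"m{i}", 0.3, 0.05, p, 5)
                for i, p in enumerate(pvals)]

    def test_highly_correlated_pair_keeps_lower_p(self):
        eff = self._effects(0.9, 0.0, 0.0)
        kept = clump_mediators(self._cands([1e-6, 1e-4, 1e-3]), eff, 0.3)
        assert [c.mediator_id for c in kept] == ["m0", "m2"]

    def test_uncorrelated_all_kept(self):
        eff = self._effects(0.0, 0.0, 0.0)
        kept = clump_mediators(self._cands([1e-6, 1e-4, 1e-3]), eff, 0.3)
        assert len(kept) == 3

    def test_greedy_trace(self):
        # corr(1,2)=0.5, corr(1,3)=0.1, corr(2,3)=0.1; p order 1 < 2 < 3
        # keep m0; drop m1 (0.5 >= 0.3 vs m0); keep m2 (0.1 vs m0)
        eff = self._effects(0.5, 0.1, 0.1)
        kept = clump_mediators(self._cands([1e-6, 1e-4, 1e-3]), eff, 0.3)
        assert [c.mediator_id for c in kept] == ["m0", "m2"]


def _mediated_region(seed=3, alphas=((0.6, 0.15),), null_transcripts=0,
                     n=100_000, theta_D=0.05):
    """Strong-signal region: sample sizes make selection of the true
    mediators essentially deterministic, while null transcripts sit far
    enough from the exposure causal cluster that LD leakage is invisible."""
    transcripts = [TranscriptBlueprint(f"tr{i}", 1_480_000 + 60_000 * i,
                                       a_em, a_my)
                   for i, (a_em, a_my) in enumerate(alphas)]
    for j in range(null_transcripts):
        transcripts.append(TranscriptBlueprint(
            f"null{j}", 1_640_000 + 20_000 * j, 0.0, 0.0))
    bp = RegionBlueprint("reg", theta_D=theta_D, transcripts=transcripts,
                         n_exposure=n, n_mediator=n, n_outcome=n)
    panel, mqtl, eqtl, gwas, truth = generate_region_fixture(bp, seed)
    return bp, panel, mqtl, eqtl, gwas, truth


class TestSelectMediators:
    def test_transcript_outside_window_excluded(self):
        bp, panel, mqtl, eqtl, gwas, _ = _mediated_region()
        far = {tid: (tab, bp.probe_pos + 600_000)
               for tid, (tab, _) in eqtl.items()}
        from mrmediate.instruments import select_instruments
        ivs = select_instruments(mqtl, panel)
        assert select_mediators(mqtl, ivs, far, panel, bp.probe_pos) == []

    def test_true_mediators_found_nulls_rejected(self):
        bp, panel, mqtl, eqtl, gwas, _ = _mediated_region(
            alphas=((0.6, 0.15), (-0.5, 0.1)), null_transcripts=4)
        from mrmediate.instruments import select_instruments
        ivs = select_instruments(mqtl, panel)
        cands = select_mediators(mqtl, ivs, eqtl, panel, bp.probe_pos)
        assert {c.mediator_id for c in cands} == {"tr0", "tr1"}

    def test_p_em_threshold_is_strict_upper_bound(self):
        bp, panel, mqtl, eqtl, gwas, _ = _mediated_region()
        from mrmediate.instruments import select_instruments
        ivs = select_instruments(mqtl, panel)
        loose = select_mediators(mqtl, ivs, eqtl, panel, bp.probe_pos,
                                 MediationConfig(p_em=1.0))
        strict = select_mediators(mqtl, ivs, eqtl, panel, bp.probe_pos,
                                  MediationConfig(p_em=1e-300))
        assert len(loose) >= 1 and strict == []


class TestMediatePair:
    def test_no_candidate_triggers_non_detectable_rule(self):
        bp, panel, mqtl, eqtl, gwas, _ = _mediated_region(
            alphas=(), null_transcripts=2)
        pair = mediate_pair(mqtl, eqtl, gwas, panel, bp.probe_pos)
        assert pair.testable and not pair.detectable
        assert pair.theta_D == pair.theta_T
        assert pair.mp_pair == 0.0

    def test_strong_mediation_recovers_truth(self):
        bp, panel, mqtl, eqtl, gwas, truth = _mediated_region(
            alphas=((0.6, 0.15),))
        pair = mediate_pair(mqtl, eqtl, gwas, panel, bp.probe_pos)
        assert pair.detectable
        assert pair.theta_T == pytest.approx(truth["theta_T"], abs=0.02)
        assert pair.mp_pair == pytest.approx(truth["true_mp"], abs=0.05)

    def test_opposite_signs_return_unclamped_mp(self):
        pair = make_pair(theta_T=0.1, theta_D=-0.02, alphas=(0.5,))
        assert pair.mp_pair == pytest.approx(1.2)

    def test_top_mediator_mode_uses_single_strongest(self):
        bp, panel, mqtl, eqtl, gwas, _ = _mediated_region(
            alphas=((0.6, 0.15), (-0.4, 0.1)))
        top = mediate_pair(mqtl, eqtl, gwas, panel, bp.probe_pos,
                           variant="top_mediator")
        assert top.n_med == 1

    def test_leave_top_iv_changes_instrument_count(self):
        bp, panel, mqtl, eqtl, gwas, _ = _mediated_region()
        full = mediate_pair(mqtl, eqtl, gwas, panel, bp.probe_pos)
        loo = mediate_pair(mqtl, eqtl, gwas, panel, bp.probe_pos,
                           variant="leave_top_iv")
        assert loo.m_uni == full.m_uni - 1


class TestEstimateMP:
    def _cohort(self):
        pairs = [make_pair(f"p{i}", theta_T=0.1 + 0.01 * i,
                           theta_D=0.06 + 0.006 * i, se_T=0.005,
                           alphas=(0.5,)) for i in range(12)]
        pairs += [make_pair(f"n{i}", theta_T=0.1, theta_D=0.1, se_T=0.005,
                            detectable=False) for i in range(4)]
        pairs.append(make_pair("nocis", has_cis_transcript=False,
                               detectable=False))
        pairs.append(make_pair("bad", testable=False, detectable=False))
        return pairs

    def test_overall_mp_below_detectable_mp(self):
        pairs = self._cohort()
        det = estimate_mp(pairs, min_pairs=2, mode="detectable")["all"]
        ova = estimate_mp(pairs, min_pairs=2, mode="overall")["all"]
        assert ova.n_pairs == det.n_pairs + 4
        assert ova.mp < det.mp

    def test_untestable_and_no_cis_pairs_never_counted(self):
        pairs = self._cohort()
        ova = estimate_mp(pairs, min_pairs=2, mode="overall")["all"]
        assert ova.n_pairs == 16

    def test_small_groups_skipped(self):
        pairs = self._cohort()
        groups = estimate_mp(pairs, lambda p: p.pair_id, min_pairs=10,
                             mode="detectable")
        assert groups == {}


class TestStratify:
    def _pairs(self):
        pairs = []
        pairs += [make_pair(f"a{i}", alphas=(-0.5,)) for i in range(3)]
        pairs += [make_pair(f"b{i}", alphas=(0.4,)) for i in range(2)]
        pairs += [make_pair(f"c{i}", alphas=(0.4, -0.2)) for i in range(4)]
        pairs += [make_pair(f"d{i}", alphas=(0.4, 0.2, 0.1))
                  for i in range(2)]
        return pairs

    def test_counts_match_construction(self):
        tab = stratify_pairs(self._pairs()).set_index(["sign",
                                                       "n_med_class"])
        assert tab.loc[("Negative", "mono"), "n"] == 3
        assert tab.loc[("Positive", "mono"), "n"] == 2
        assert tab.loc[("Bivalent", "multi"), "n"] == 4
        assert tab.loc[("Positive", "multi"), "n"] == 2

    def test_mono_cannot_be_bivalent(self):
        tab = stratify_pairs(self._pairs()).set_index(["sign",
                                                       "n_med_class"])
        assert tab.loc[("Bivalent", "mono"), "n"] == 0

    def test_mean_mediator_count_per_stratum(self):
        tab = stratify_pairs(self._pairs()).set_index(["sign",
                                                       "n_med_class"])
        assert tab.loc[("Positive", "multi"), "mean_n_med"] == 3.0
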