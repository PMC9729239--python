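"""Mediator selection, per-pair mediation analysis and aggregation of
mediation proportions (MPs).

For one exposure-outcome pair the total causal effect theta_T comes from
univariable IVW MR on exposure instruments and the direct effect theta_D
from MVMR jointly modelling the exposure and its selected cis mediators.
The per-pair MP is 1 - theta_D/theta_T (unclamped). Group MPs are never
averages of per-pair MPs: they come from the no-intercept regression of
theta_D on theta_T, whose slope gamma is corrected for regression-dilution
bias caused by noise in theta_T:

    gamma_cor = gamma / sqrt(1 - sum(SE^2(theta_T)) / sum(theta_T^2))

and MP = 1 - gamma_cor. Two group MPs are compared with a z-test on the
corrected slopes (independence assumed, so p-values may be lenient).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .instruments import SteigerConfig, select_instruments, steiger_filter
from .io import LDPanel, SummaryStatsTable
from .ivw import InstrumentSet, IVWModel
from .mvmr import (MVMRModel, UntestablePairError, build_design_matrix,
                   rank_score_clump)

log = logging.getLogger(__name__)


@dataclass
class MediationConfig:
    """Thresholds governing one mediation analysis."""

    p_iv: float = 1e-6              # instrument significance
    r2_iv: float = 0.05             # instrument LD-pruning threshold
    min_ivs: int = 5                # exposure IVs required at selection
    min_ivs_post_steiger: int = 3   # exposure IVs required after filtering
    p_em: float = 0.01              # mediator selection threshold
    cis_window_iv: int = 1_000_000      # IV window around the feature (bp)
    cis_window_mediators: int = 500_000  # mediator TSS window (bp)
    r_med: float = 0.3              # mediator correlation clump (variant mode)
    steiger: SteigerConfig = field(default_factory=SteigerConfig)


@dataclass
class MediatorCandidate:
    """A cis transcript causally associated with the exposure."""

    mediator_id: str
    alpha_EM: float
    se_EM: float
    p_EM: float
    n_ivs_EM: int
    tss_distance: int | None = None
    alpha_MY: float | None = None
    se_MY: float | None = None
    alpha_MY_source: str = "mvmr"

    def __post_init__(self):
        if not (0 < self.p_EM <= 1):
            raise ValueError("p_EM must be in (0, 1]")


@dataclass
class PairResult:
    """Mediation result for one exposure-outcome pair."""

    pair_id: str
    exposure_id: str
    outcome_id: str
    theta_T: float
    se_T: float
    p_T: float
    theta_D: float
    se_D: float
    mediators: list[MediatorCandidate] = field(default_factory=list)
    detectable: bool = False
    has_cis_transcript: bool = True
    testable: bool = True
    f_cond: float | None = None
    q_uni: tuple[float, int, float] | None = None
    q_mvmr: tuple[float, int, float] | None = None
    m_uni: int = 0
    m_mvmr: int = 0
    variant: str = "full"
    note: str = ""

    def __post_init__(self):
        if not self.detectable and self.testable:
            # non-detectable rule: theta_D := theta_T, MP := 0
            self.theta_D = self.theta_T

    @property
    def n_med(self) -> int:
        return len(self.mediators)

    @property
    def mp_pair(self) -> float:
        """Per-pair MP, 1 - theta_D/theta_T, unclamped (may fall outside
        [0, 1] when the two estimates have opposite sign)."""
        if not self.detectable:
            return 0.0
        return 1.0 - self.theta_D / self.theta_T

    @property
    def alpha_em_sign_class(self) -> str:
        signs = {np.sign(m.alpha_EM) for m in self.mediators}
        if signs <= {1.0}:
            return "Positive"
        if signs <= {-1.0}:
            return "Negative"
        return "Bivalent"


@dataclass
class MPEstimate:
    """Group-level mediation proportion from the corrected slope."""

    group_id: str
    n_pairs: int
    gamma: float
    se_gamma: float
    gamma_cor: float
    se_gamma_cor: float

    @property
    def mp(self) -> float:
        return 1.0 - self.gamma_cor

    @property
    def ci95(self) -> tuple[float, float]:
        half = 1.96 * self.se_gamma_cor
        return (self.mp - half, self.mp + half)

    def summary(self) -> str:
        lo, hi = self.ci95
        return (f"MP[{self.group_id}] = {100 * self.mp:.1f}% "
                f"(95% CI: [{100 * lo:.1f}%-{100 * hi:.1f}%], "
                f"n={self.n_pairs} pairs)")


class MPRegression:
    """No-intercept regression of direct on total effects with
    regression-dilution correction.

    Parameters
    ----------
    theta_T, theta_D : array-like
        Per-pair total and direct effect estimates.
    se_T : array-like
        Standard errors of the total effects (drives the dilution term).
    """

    def __init__(self, theta_T, theta_D, se_T, group_id: str = "all"):
        self.theta_T = np.asarray(theta_T, float)
        self.theta_D = np.asarray(theta_D, float)
        self.se_T = np.asarray(se_T, float)
        self.group_id = group_id
        if not (len(self.theta_T) == len(self.theta_D) == len(self.se_T)):
            raise ValueError("input vectors must have equal length")
        if len(self.theta_T) == 0:
            raise ValueError("at least one pair required")

    def fit(self) -> MPEstimate:
        tT, tD, seT = self.theta_T, self.theta_D, self.se_T
        n = len(tT)
        ss_T = float(np.sum(tT ** 2))
        gamma = float(np.sum(tD * tT)) / ss_T
        resid = tD - gamma * tT
        s2 = float(np.sum(resid ** 2)) / max(n - 1, 1)
        se_gamma = float(np.sqrt(s2 / ss_T))
        shrink = 1.0 - float(np.sum(seT ** 2)) / ss_T
        if shrink <= 0:
            raise ValueError(
                "dilution correction undefined: sum SE^2(theta_T) >= "
                "sum theta_T^2")
        root = np.sqrt(shrink)
        return MPEstimate(self.group_id, n, gamma, se_gamma,
                          gamma / root, se_gamma / root)


def select_mediators(exposure: SummaryStatsTable, exposure_ivs: Sequence[str],
                     transcripts: Mapping[str, tuple[SummaryStatsTable, int]],
                     ld: LDPanel, probe_pos: int,
                     cfg: MediationConfig | None = None,
                     ) -> list[MediatorCandidate]:
    """Univariable MR of the exposure on every cis transcript; transcripts
    with p_EM below the threshold are retained as mediator candidates.

    ``transcripts`` maps transcript ID to (summary table, TSS position).
    Exposure IVs are Steiger-filtered against each candidate transcript
    before its MR; candidates with fewer than the minimum surviving IVs
    are skipped.
    """
    cfg = cfg or MediationConfig()
    out: list[MediatorCandidate] = []
    exp_idx = exposure.df.set_index("variant_id")
    for tid, (tab, tss) in transcripts.items():
        dist = abs(int(tss) - int(probe_pos))
        if dist > cfg.cis_window_mediators:
            continue
        ivs = list(exposure_ivs)
        bE = exp_idx.loc[ivs, "beta"].to_numpy(float)
        vE = exp_idx.loc[ivs, "se"].to_numpy(float) ** 2
        med_idx = tab.df.set_index("variant_id")
        bM = np.array([float(med_idx.loc[v, "beta"]) if v in med_idx.index
                       else 0.0 for v in ivs])
        n_med = float(np.median(tab.df["n"]))
        vM = np.array([float(med_idx.loc[v, "se"]) ** 2 if v in med_idx.index
                       else 1.0 / n_med for v in ivs])
        mask = steiger_filter(bE, vE, bM, vM, cfg.steiger)
        if int(mask.sum()) < cfg.min_ivs_post_steiger:
            continue
        sub = [v for v, ok in zip(ivs, mask) if ok]
        res = IVWModel(InstrumentSet(
            f"{exposure.trait_id}->{tid}", sub, bE[mask], vE[mask],
            bM[mask], vM[mask], ld.submatrix(sub))).fit()
        if res.pvalue < cfg.p_em:
            out.append(MediatorCandidate(
                tid, res.theta, res.se, res.pvalue, res.m,
                tss_distance=dist))
    out.sort(key=lambda c: c.p_EM)
    return out


def mediator_effect_matrix(cands: Sequence[MediatorCandidate],
                           transcripts: Mapping[str, tuple[SummaryStatsTable, int]],
                           iv_ids: Sequence[str]) -> pd.DataFrame:
    """Per-mediator QTL effect vectors over a shared IV set (zeros where
    unreported), used to correlate mediators with one another."""
    cols = {}
    for c in cands:
        tab = transcripts[c.mediator_id][0].df.set_index("variant_id")["beta"]
        cols[c.mediator_id] = [float(tab[v]) if v in tab.index else 0.0
                               for v in iv_ids]
    return pd.DataFrame(cols, index=list(iv_ids))


def clump_mediators(cands: Sequence[MediatorCandidate],
                    effects: pd.DataFrame,
                    r_med: float = 0.3) -> list[MediatorCandidate]:
    """Greedy retention of mediators by ascending p_EM; candidates whose
    QTL-effect correlation with an already-kept mediator reaches
    ``r_med`` in absolute value are dropped."""
    kept: list[MediatorCandidate] = []
    for c in sorted(cands, key=lambda c: c.p_EM):
        ok = True
        for other in kept:
            x = effects[c.mediator_id].to_numpy(float)
            y = effects[other.mediator_id].to_numpy(float)
            use = (x != 0) | (y != 0)
            if int(use.sum()) < 2:
                warnings.warn(
                    f"<2 shared IVs to correlate {c.mediator_id} and "
                    f"{other.mediator_id}; treated as uncorrelated",
                    stacklevel=2)
                continue
            sx, sy = np.std(x[use]), np.std(y[use])
            r = 0.0 if sx == 0 or sy == 0 else float(np.corrcoef(x[use], y[use])[0, 1])
            if abs(r) >= r_med:
                ok = False
                break
        if ok:
            kept.append(c)
    return kept


def _steiger_vs_outcome(ivs, src_idx, out_idx, cfg):
    bX = src_idx.loc[ivs, "beta"].to_numpy(float)
    vX = src_idx.loc[ivs, "se"].to_numpy(float) ** 2
    bY = np.array([float(out_idx.loc[v, "beta"]) if v in out_idx.index else 0.0
                   for v in ivs])
    vY = np.array([float(out_idx.loc[v, "se"]) ** 2 if v in out_idx.index
                   else np.median(out_idx["se"]) ** 2 for v in ivs])
    mask = steiger_filter(bX, vX, bY, vY, cfg.steiger)
    return [v for v, ok in zip(ivs, mask) if ok]


def mediate_pair(exposure: SummaryStatsTable,
                 transcripts: Mapping[str, tuple[SummaryStatsTable, int]],
                 outcome: SummaryStatsTable, ld: LDPanel, probe_pos: int,
                 cfg: MediationConfig | None = None,
                 variant: str = "full",
                 exposure_ivs: Sequence[str] | None = None) -> PairResult:
    """Full mediation analysis of one exposure-outcome pair.

    Runs instrument selection, Steiger filtering, univariable IVW for
    theta_T, mediator selection, rank-score instrument pooling, the MVMR
    fit for theta_D and the conditional-F/heterogeneity diagnostics.

    ``variant`` selects a sensitivity mode: ``full`` (default),
    ``top_mediator`` (lowest-p_EM transcript as sole mediator),
    ``uncorrelated`` (mediators clumped at r_med first) or
    ``leave_top_iv`` (strongest exposure IV removed from both theta_T and
    theta_D).
    """
    cfg = cfg or MediationConfig()
    pair_id = f"{exposure.trait_id}|{outcome.trait_id}"
    exp_idx = exposure.df.set_index("variant_id")
    out_idx = outcome.df.set_index("variant_id")

    def untestable(note, has_cis=True):
        return PairResult(pair_id, exposure.trait_id, outcome.trait_id,
                          np.nan, np.nan, np.nan, np.nan, np.nan,
                          testable=False, detectable=False,
                          has_cis_transcript=has_cis, variant=variant,
                          note=note)

    if exposure_ivs is None:
        window = (probe_pos - cfg.cis_window_iv, probe_pos + cfg.cis_window_iv)
        exposure_ivs = select_instruments(exposure, ld, cfg.p_iv, cfg.r2_iv,
                                          window)
        if len(exposure_ivs) < cfg.min_ivs:
            return untestable(f"only {len(exposure_ivs)} selected IVs "
                              f"(< {cfg.min_ivs})")
    # outcome table is assumed complete; IVs it lacks cannot be used
    exposure_ivs = [v for v in exposure_ivs if v in out_idx.index]

    # Steiger vs outcome
    ivs = _steiger_vs_outcome(exposure_ivs, exp_idx, out_idx, cfg)
    if variant == "leave_top_iv" and ivs:
        top = min(ivs, key=lambda v: float(exp_idx.loc[v, "pvalue"]))
        ivs = [v for v in ivs if v != top]
    if len(ivs) < cfg.min_ivs_post_steiger:
        return untestable(f"only {len(ivs)} exposure IVs post-Steiger")

    cis = {tid: (tab, tss) for tid, (tab, tss) in transcripts.items()
           if abs(int(tss) - int(probe_pos)) <= cfg.cis_window_mediators}
    has_cis = bool(cis)
    cands = select_mediators(exposure, ivs, cis, ld, probe_pos, cfg)

    if variant == "top_mediator" and cands:
        cands = [cands[0]]
    elif variant == "uncorrelated" and len(cands) > 1:
        effects = mediator_effect_matrix(cands, cis, ivs)
        cands = clump_mediators(cands, effects, cfg.r_med)

    # Steiger of exposure IVs against every retained mediator
    for c in cands:
        med_idx = cis[c.mediator_id][0].df.set_index("variant_id")
        bE = exp_idx.loc[ivs, "beta"].to_numpy(float)
        vE = exp_idx.loc[ivs, "se"].to_numpy(float) ** 2
        n_med = float(np.median(cis[c.mediator_id][0].df["n"]))
        bM = np.array([float(med_idx.loc[v, "beta"]) if v in med_idx.index
                       else 0.0 for v in ivs])
        vM = np.array([float(med_idx.loc[v, "se"]) ** 2 if v in med_idx.index
                       else 1.0 / n_med for v in ivs])
        mask = steiger_filter(bE, vE, bM, vM, cfg.steiger)
        ivs = [v for v, ok in zip(ivs, mask) if ok]
    if len(ivs) < cfg.min_ivs_post_steiger:
        return untestable(f"only {len(ivs)} exposure IVs after mediator "
                          "Steiger filtering")

    # total effect
    bE = exp_idx.loc[ivs, "beta"].to_numpy(float)
    vE = exp_idx.loc[ivs, "se"].to_numpy(float) ** 2
    bY = out_idx.loc[[v for v in ivs], "beta"].to_numpy(float)
    vY = out_idx.loc[[v for v in ivs], "se"].to_numpy(float) ** 2
    uni = IVWModel(InstrumentSet(pair_id, ivs, bE, vE, bY, vY,
                                 ld.submatrix(ivs))).fit()
    q_uni = uni.q_statistic() if uni.m >= 2 else None

    n_E = float(np.median(exposure.df["n"]))
    if not cands:
        return PairResult(pair_id, exposure.trait_id, outcome.trait_id,
                          uni.theta, uni.se, uni.pvalue, uni.theta, uni.se,
                          detectable=False, has_cis_transcript=has_cis,
                          q_uni=q_uni, m_uni=uni.m, variant=variant)

    # mediator instruments (own cis IVs, Steiger-filtered vs outcome)
    med_iv_stats: dict[str, SummaryStatsTable] = {}
    med_own_ivs: dict[str, list[str]] = {}
    for c in cands:
        tab, tss = cis[c.mediator_id]
        win = (tss - cfg.cis_window_iv, tss + cfg.cis_window_iv)
        own = select_instruments(tab, ld, cfg.p_iv, cfg.r2_iv, win)
        own = [v for v in own if v in out_idx.index]
        own = _steiger_vs_outcome(own, tab.df.set_index("variant_id"),
                                  out_idx, cfg)
        med_own_ivs[c.mediator_id] = own
        if own:
            med_iv_stats[c.mediator_id] = tab.subset(own)

    pooled = rank_score_clump(ivs, med_iv_stats, ld, cfg.r2_iv)
    prob = build_design_matrix(
        exposure, {c.mediator_id: cis[c.mediator_id][0] for c in cands},
        outcome, pooled, ld, pair_id)
    try:
        mv = MVMRModel(prob, cfg.min_ivs_post_steiger).fit()
    except UntestablePairError as err:
        return untestable(str(err))
    q_mvmr = mv.q_statistic() if mv.m > mv.k else None
    n_M = float(np.median(np.concatenate(
        [cis[c.mediator_id][0].df["n"].to_numpy(float) for c in cands])))
    f_cond = mv.conditional_f(n_E, n_M=n_M)

    # mediator -> outcome effects: univariable when >= 3 own instruments
    for c in cands:
        own = med_own_ivs.get(c.mediator_id, [])
        if len(own) >= 3:
            tab = cis[c.mediator_id][0]
            t_idx = tab.df.set_index("variant_id")
            bM = t_idx.loc[own, "beta"].to_numpy(float)
            vM = t_idx.loc[own, "se"].to_numpy(float) ** 2
            bYo = out_idx.loc[own, "beta"].to_numpy(float)
            vYo = out_idx.loc[own, "se"].to_numpy(float) ** 2
            r = IVWModel(InstrumentSet(f"{c.mediator_id}->Y", own, bM, vM,
                                       bYo, vYo, ld.submatrix(own))).fit()
            c.alpha_MY, c.se_MY, c.alpha_MY_source = r.theta, r.se, "univariable"
        elif c.mediator_id in mv.alpha_MY:
            c.alpha_MY, c.se_MY = mv.alpha_MY[c.mediator_id]
            c.alpha_MY_source = "mvmr"

    return PairResult(pair_id, exposure.trait_id, outcome.trait_id,
                      uni.theta, uni.se, uni.pvalue, mv.theta_D, mv.se_D,
                      mediators=list(cands), detectable=True,
                      has_cis_transcript=has_cis, f_cond=f_cond,
                      q_uni=q_uni, q_mvmr=q_mvmr, m_uni=uni.m, m_mvmr=mv.m,
                      variant=variant)


def estimate_mp(pairs: Sequence[PairResult],
                grouping: Callable[[PairResult], str] | None = None,
                min_pairs: int = 10,
                mode: str = "detectable") -> dict[str, MPEstimate]:
    """Group-level MPs via the dilution-corrected no-intercept slope.

    ``mode='detectable'`` uses pairs with at least one selected mediator;
    ``mode='overall'`` additionally includes testable pairs without one
    (their theta_D equals theta_T by the non-detectable rule). Pairs
    without any cis transcript, or untestable pairs, never contribute.
    Groups with fewer than ``min_pairs`` pairs are skipped.
    """
    if mode not in {"detectable", "overall"}:
        raise ValueError("mode must be 'detectable' or 'overall'")
    usable = [p for p in pairs if p.testable and p.has_cis_transcript]
    if mode == "detectable":
        usable = [p for p in usable if p.detectable]
    groups: dict[str, list[PairResult]] = {}
    for p in usable:
        key = grouping(p) if grouping else "all"
        groups.setdefault(key, []).append(p)
    out: dict[str, MPEstimate] = {}
    for key, members in groups.items():
        if len(members) < min_pairs:
            log.info("group %s skipped: %d pairs < %d", key, len(members),
                     min_pairs)
            continue
        try:
            out[key] = MPRegression(
                [p.theta_T for p in members],
                [p.theta_D for p in members],
                [p.se_T for p in members], group_id=key).fit()
        except ValueError as err:
            log.warning("group %s skipped: %s", key, err)
    return out


def compare_mp(a: MPEstimate, b: MPEstimate) -> tuple[float, float]:
    """Two-sided z-test for a difference between two group MPs, based on
    the dilution-corrected slopes. Assumes independence of the two
    estimates, so p-values may be lenient for overlapping pair sets."""
    if a.se_gamma_cor <= 0 or b.se_gamma_cor <= 0:
        raise ValueError("non-positive standard errors")
    z = (a.gamma_cor - b.gamma_cor) / np.hypot(a.se_gamma_cor, b.se_gamma_cor)
    return float(z), float(2 * stats.norm.sf(abs(z)))


def product_of_coefficients(pair: PairResult) -> tuple[float, float]:
    """Indirect effect by the product method, sum_k alpha_EM,k * alpha_MY,k,
    and the implied direct effect theta_T - theta_M."""
    theta_M = 0.0
    for c in pair.mediators:
        if c.alpha_MY is None:
            warnings.warn(f"{c.mediator_id}: no alpha_MY available; skipped",
                          stacklevel=2)
            continue
        theta_M += c.alpha_EM * c.alpha_MY
    return theta_M, pair.theta_T - theta_M


def stratify_pairs(pairs: Sequence[PairResult],
                   min_pairs: int = 1) -> pd.DataFrame:
    """Stratify detectable pairs by mediator-count class (mono/multi) and
    the sign pattern of the exposure-to-mediator effects
    (Negative/Positive/Bivalent); mono pairs cannot be Bivalent.

    Returns one row per stratum with n, MP (corrected-slope estimate, NaN
    when the stratum is empty or too small) and mean mediator count.
    """
    det = [p for p in pairs if p.testable and p.detectable and p.n_med >= 1]
    rows = []
    for sign in ("Negative", "Positive", "Bivalent"):
        for multi in ("mono", "multi"):
            if sign == "Bivalent" and multi == "mono":
                members: list[PairResult] = []
            else:
                members = [p for p in det
                           if p.alpha_em_sign_class == sign
                           and ((p.n_med == 1) == (multi == "mono"))]
            mp = ci_lo = ci_hi = np.nan
            if len(members) >= max(min_pairs, 2):
                try:
                    est = MPRegression([p.theta_T for p in members],
                                       [p.theta_D for p in members],
                                       [p.se_T for p in members],
                                       group_id=f"{sign}/{multi}").fit()
                    mp, (ci_lo, ci_hi) = est.mp, est.ci95
                except ValueError:
                    pass
            rows.append({
                "sign": sign, "n_med_class": multi, "n": len(members),
                "mp": mp, "ci_lo": ci_lo, "ci_hi": ci_hi,
                "mean_n_med": (np.mean([p.n_med for p in members])
                               if members else np.nan)})
    return pd.DataFrame(rows)


def pairs_to_table(pairs: Sequence[PairResult]) -> pd.DataFrame:
    """Tab-delimited-ready per-pair results table."""
    rows = []
    for p in pairs:
        rows.append({
            "pair_id": p.pair_id, "exposure": p.exposure_id,
            "outcome": p.outcome_id, "variant": p.variant,
            "testable": p.testable, "detectable": p.detectable,
            "has_cis_transcript": p.has_cis_transcript,
            "m_uni": p.m_uni, "m_mvmr": p.m_mvmr, "n_med": p.n_med,
            "theta_T": p.theta_T, "se_T": p.se_T, "p_T": p.p_T,
            "theta_D": p.theta_D, "se_D": p.se_D,
            "mp_pair": p.mp_pair if p.testable else np.nan,
            "f_cond": p.f_cond,
            "Q_uni": p.q_uni[0] if p.q_uni else np.nan,
            "Q_uni_p": p.q_uni[2] if p.q_uni else np.nan,
            "Q_mvmr": p.q_mvmr[0] if p.q_mvmr else np.nan,
            "Q_mvmr_p": p.q_mvmr[2] if p.q_mvmr else np.nan,
            "mediators": ",".join(m.mediator_id for m in p.mediators),
            "note": p.note})
    return pd.DataFrame(rows)
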