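"""Generative simulation engine for assessing bias in estimated mediation
proportions.

One replicate draws a molecular exposure instrumented by m_E independent
IVs (effects rescaled to a total cis-heritability h2_E), N_med_pot
potential mediators of which N_med carry true exposure->mediator and
mediator->outcome effects (alpha_EM, alpha_MY) drawn from a bivariate
normal with correlation rho, and composes outcome effects from the causal
chain with a prescribed true mediation proportion MP. Sampling noise with
variance 1/N is added to every effect vector and the exposure effects of
mediator instruments are then re-zeroed, mimicking mQTL tables that only
report significant associations. The full estimator chain (univariable
IVW, mediator selection at P_EM, MVMR, conditional F) is run per
replicate, and replicate-level (theta_T, theta_D) estimates are pooled
into an MP estimate through the dilution-corrected no-intercept slope.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .ivw import IVWModel
from .mediation import MPEstimate, MPRegression
from .mvmr import MVMRModel, MVMRProblem, conditional_f


@dataclass
class SimulationConfig:
    """Parameters of the generative model.

    Defaults are calibrated to the regime of real whole-blood cis-QTL
    data: ten instruments each for the exposure and for every relevant
    mediator, an exposure cis-heritability of 0.1, weak-ish mediator
    direct heritability of 0.03 and QTL/GWAS sample sizes of 30,000
    (see docs/methods.md for the calibration).
    """

    m_E: int = 10                 # exposure instruments
    m_M: int = 10                 # instruments per relevant mediator
    N_med_pot: int = 12           # potential mediators tested
    N_med: int = 2                # truly relevant mediators
    h2_E: float = 0.1             # exposure cis-heritability
    h2_M_direct: float = 0.03     # per-mediator direct cis-heritability
    var_alpha_EM: float = 0.075   # var of exposure->mediator effects
    var_alpha_MY: float = 0.05    # var of mediator->outcome effects
    rho: float = 0.0              # corr(alpha_EM, alpha_MY)
    true_MP: float = 0.35         # generative mediation proportion
    N_E: int = 30_000             # exposure QTL sample size
    N_M: int = 30_000             # mediator QTL sample size
    N_Y: int = 30_000             # outcome GWAS sample size
    p_em: float = 0.01            # mediator selection threshold
    theta_D_null: float = 0.1     # direct effect used when no mediation
    reps: int = 500
    seed: int | None = None

    def __post_init__(self):
        if not (0 < self.h2_E < 1 and 0 < self.h2_M_direct < 1):
            raise ValueError("heritabilities must lie in (0, 1)")
        if abs(self.rho) > 1:
            raise ValueError("|rho| must be <= 1")
        if self.N_med > self.N_med_pot:
            raise ValueError("N_med must not exceed N_med_pot")
        if self.true_MP == 0 and self.N_med > 0:
            raise ValueError("true_MP=0 with relevant mediators leaves the "
                             "direct effect undefined")

    @property
    def m_total(self) -> int:
        # every potential mediator has its own instruments; non-mediators
        # differ only in their causal effects being zero
        return self.m_E + self.N_med_pot * self.m_M


@dataclass
class SimulatedSummaryStats:
    """Noisy effect vectors for one replicate, plus the generative truth."""

    beta_E_hat: np.ndarray                 # length m_E + N_med_pot*m_M
    beta_M_hat: np.ndarray                 # (N_med_pot, same length)
    beta_Y_hat: np.ndarray
    truth: dict

    @property
    def m(self) -> int:
        return len(self.beta_E_hat)


def _rescaled_normal(rng, scale2: float, size: int) -> np.ndarray:
    """Draw normal effects and rescale so their squares sum to scale2."""
    b = rng.normal(0.0, np.sqrt(scale2 / size), size)
    return b * np.sqrt(scale2 / np.sum(b ** 2))


def simulate_dataset(cfg: SimulationConfig,
                     rng: np.random.Generator | int | None = None
                     ) -> SimulatedSummaryStats:
    """Draw one replicate of the generative model."""
    rng = np.random.default_rng(rng)
    m = cfg.m_total
    beta_E = np.zeros(m)
    beta_E[:cfg.m_E] = _rescaled_normal(rng, cfg.h2_E, cfg.m_E)

    cov = np.array([
        [cfg.var_alpha_EM,
         cfg.rho * np.sqrt(cfg.var_alpha_EM * cfg.var_alpha_MY)],
        [cfg.rho * np.sqrt(cfg.var_alpha_EM * cfg.var_alpha_MY),
         cfg.var_alpha_MY]])
    alpha_EM = np.zeros(cfg.N_med_pot)
    alpha_MY = np.zeros(cfg.N_med_pot)
    if cfg.N_med:
        draws = rng.multivariate_normal(np.zeros(2), cov, size=cfg.N_med)
        alpha_EM[:cfg.N_med] = draws[:, 0]
        alpha_MY[:cfg.N_med] = draws[:, 1]

    beta_M = np.zeros((cfg.N_med_pot, m))
    for k in range(cfg.N_med_pot):
        beta_M[k, :cfg.m_E] = beta_E[:cfg.m_E] * alpha_EM[k]
        lo = cfg.m_E + k * cfg.m_M
        beta_M[k, lo:lo + cfg.m_M] = _rescaled_normal(
            rng, cfg.h2_M_direct, cfg.m_M)

    theta_M = float(np.sum(alpha_EM * alpha_MY))
    if theta_M == 0.0:
        theta_D = cfg.theta_D_null
    else:
        theta_D = theta_M * (1.0 / cfg.true_MP - 1.0)
    theta_T = theta_D + theta_M

    beta_Y = theta_D * beta_E + alpha_MY @ beta_M

    beta_E_hat = beta_E + rng.normal(0, 1 / np.sqrt(cfg.N_E), m)
    beta_M_hat = beta_M + rng.normal(0, 1 / np.sqrt(cfg.N_M),
                                     (cfg.N_med_pot, m))
    beta_Y_hat = beta_Y + rng.normal(0, 1 / np.sqrt(cfg.N_Y), m)
    # mQTL-style reporting: exposure effects of mediator IVs unreported
    beta_E_hat[cfg.m_E:] = 0.0

    truth = {"alpha_EM": alpha_EM, "alpha_MY": alpha_MY,
             "theta_M": theta_M, "theta_D": theta_D, "theta_T": theta_T,
             "relevant": np.arange(cfg.N_med)}
    return SimulatedSummaryStats(beta_E_hat, beta_M_hat, beta_Y_hat, truth)


def estimate_replicate(sim: SimulatedSummaryStats,
                       cfg: SimulationConfig) -> dict:
    """Run the full estimator chain on one simulated replicate."""
    mE = cfg.m_E
    var_E = 1.0 / cfg.N_E
    var_M = 1.0 / cfg.N_M
    var_Y = 1.0 / cfg.N_Y
    bE = sim.beta_E_hat[:mE]

    uni = IVWModel.from_arrays(bE, np.full(mE, var_E),
                               sim.beta_Y_hat[:mE], np.full(mE, var_Y)).fit()

    selected: list[int] = []
    for j in range(cfg.N_med_pot):
        r = IVWModel.from_arrays(bE, np.full(mE, var_E),
                                 sim.beta_M_hat[j, :mE],
                                 np.full(mE, var_M)).fit()
        if r.pvalue < cfg.p_em:
            selected.append(j)

    relevant = set(sim.truth["relevant"].tolist())
    n_sig_rel = len([j for j in selected if j in relevant])

    if not selected:
        return {"theta_T": uni.theta, "se_T": uni.se, "theta_D": uni.theta,
                "n_selected": 0, "n_med_sig": 0, "f_cond": np.nan,
                "detectable": False}

    rows = list(range(mE))
    for j in selected:
        lo = mE + j * cfg.m_M
        rows.extend(range(lo, lo + cfg.m_M))
    rows = np.array(rows)
    B = np.column_stack([sim.beta_E_hat[rows]] +
                        [sim.beta_M_hat[j, rows] for j in selected])
    prob = MVMRProblem("sim", [f"iv{i}" for i in rows], B,
                       sim.beta_Y_hat[rows], np.full(len(rows), var_Y),
                       np.eye(len(rows)),
                       mediator_ids=[f"M{j}" for j in selected])
    mv = MVMRModel(prob, min_exposure_ivs=3).fit()
    f_cond = conditional_f(prob, cfg.N_E, n_M=cfg.N_M)
    return {"theta_T": uni.theta, "se_T": uni.se, "theta_D": mv.theta_D,
            "n_selected": len(selected), "n_med_sig": n_sig_rel,
            "f_cond": f_cond, "detectable": True}


@dataclass
class ScenarioResult:
    """Aggregated estimates over the replicates of one scenario."""

    config: SimulationConfig
    mp_estimate: MPEstimate
    mean_n_med_sig: float
    mean_n_selected: float
    mean_f_cond: float
    replicates: pd.DataFrame = field(repr=False)
    n_failed: int = 0

    @property
    def mean_mp_hat(self) -> float:
        return self.mp_estimate.mp

    @property
    def ci95_mp_hat(self) -> tuple[float, float]:
        return self.mp_estimate.ci95

    @property
    def mc_se_mp(self) -> float:
        """Jackknife Monte-Carlo SE of the scenario MP.

        Replicates are left out one at a time and the full
        dilution-corrected slope recomputed, which captures both the
        heteroskedastic replicate residuals and the reuse of the noisy
        total effects inside the correction factor — sources the analytic
        homoskedastic SE does not see.
        """
        tT = self.replicates["theta_T"].to_numpy(float)
        tD = self.replicates["theta_D"].to_numpy(float)
        seT = self.replicates["se_T"].to_numpy(float)
        n = len(tT)
        S_dt = float(np.sum(tD * tT))
        S_tt = float(np.sum(tT ** 2))
        S_ee = float(np.sum(seT ** 2))
        gamma_i = (S_dt - tD * tT) / (S_tt - tT ** 2)
        shrink_i = 1.0 - (S_ee - seT ** 2) / (S_tt - tT ** 2)
        mp_i = 1.0 - gamma_i / np.sqrt(np.maximum(shrink_i, 1e-12))
        return float(np.sqrt((n - 1) / n * np.sum((mp_i - mp_i.mean()) ** 2)))

    def summary(self) -> str:
        lo, hi = self.ci95_mp_hat
        return (f"Scenario: true MP={self.config.true_MP}, "
                f"N_med={self.config.N_med}/{self.config.N_med_pot}, "
                f"reps={len(self.replicates)}\n"
                f"  MP_hat = {100 * self.mean_mp_hat:.1f}% "
                f"(95% CI: [{100 * lo:.1f}%-{100 * hi:.1f}%])\n"
                f"  mean N_med,sig = {self.mean_n_med_sig:.2f}\n"
                f"  mean conditional F = {self.mean_f_cond:.1f}")


def run_scenario(cfg: SimulationConfig,
                 seed: int | None = None) -> ScenarioResult:
    """Simulate ``cfg.reps`` exposure-outcome pairs and pool them into one
    MP estimate. Deterministic for a fixed seed; per-replicate streams are
    derived from the master seed by replicate index."""
    if cfg.reps < 2:
        raise ValueError("at least 2 replicates required")
    master = seed if seed is not None else cfg.seed
    streams = np.random.SeedSequence(master).spawn(cfg.reps)
    records = []
    n_failed = 0
    for ss in streams:
        try:
            sim = simulate_dataset(cfg, np.random.default_rng(ss))
            records.append(estimate_replicate(sim, cfg))
        except (np.linalg.LinAlgError, ValueError):
            n_failed += 1
    reps = pd.DataFrame(records)
    est = MPRegression(reps["theta_T"], reps["theta_D"], reps["se_T"],
                       group_id="scenario").fit()
    return ScenarioResult(cfg, est,
                          float(reps["n_med_sig"].mean()),
                          float(reps["n_selected"].mean()),
                          float(reps["f_cond"].mean(skipna=True)),
                          reps, n_failed)


def sweep(cfgs: Sequence[SimulationConfig], seed: int | None = None,
          varied: str | None = None) -> pd.DataFrame:
    """One scenario per config; returns a tidy table keyed by the varied
    parameter (auto-detected when not named)."""
    if varied is None and len(cfgs) > 1:
        base = cfgs[0]
        for name in vars(base):
            if any(getattr(c, name) != getattr(base, name) for c in cfgs[1:]):
                varied = name
                break
    rows = []
    for i, cfg in enumerate(cfgs):
        res = run_scenario(cfg, None if seed is None else seed + i)
        lo, hi = res.ci95_mp_hat
        rows.append({
            "scenario": i,
            "varied_param": varied,
            "varied_value": getattr(cfg, varied) if varied else None,
            "true_mp": cfg.true_MP,
            "mp_hat": res.mean_mp_hat, "mp_ci_lo": lo, "mp_ci_hi": hi,
            "mean_n_med_sig": res.mean_n_med_sig,
            "mean_n_selected": res.mean_n_selected,
            "mean_f_cond": res.mean_f_cond,
            "n_failed": res.n_failed})
    return pd.DataFrame(rows)


def default_scenario(**overrides) -> SimulationConfig:
    """The calibrated default scenario (true MP 0.35, 2 of 12 mediators)."""
    return replace(SimulationConfig(), **overrides)
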