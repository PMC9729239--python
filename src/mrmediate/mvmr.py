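"""Multivariable Mendelian randomization (MVMR).

Pooled exposure- and mediator-associated instruments are regressed jointly:

    theta_D_vec = (B' C^-1 B)^-1 B' C^-1 b_Y

where B has the exposure IV effects in its first column and one column of
IV effects per mediator. The first element of theta_D_vec is the direct
(unmediated) effect of the exposure on the outcome; the remaining elements
are mediator direct effects (alpha_MY). Effects unreported in a source
table (below its reporting threshold) enter B as exact zeros, which keeps
regression-dilution from weak, noisy entries out of the design.

Weak-instrument strength of the exposure conditional on the mediators is
measured by a Sanderson-style conditional F-statistic computed from the
residuals of the (C^-1-weighted) regression of the exposure IV-effect
column on the mediator columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ._linalg import inverse_sqrt, regularized_inverse
from .io import LDPanel, SummaryStatsTable

log = logging.getLogger(__name__)

#: Relative singular-value threshold below which mediator columns are
#: treated as collinear and dropped.
COLLINEARITY_TOL = 1e-10


class UntestablePairError(ValueError):
    """Raised when a pair has too few exposure instruments to test."""


@dataclass
class MVMRProblem:
    """Design matrix and outcome vector for one multivariable fit."""

    pair_id: str
    iv_ids: list[str]
    B: np.ndarray            # m x (k+1); column 0 = exposure
    beta_Y: np.ndarray
    var_Y: np.ndarray
    C: np.ndarray
    mediator_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.B = np.atleast_2d(np.asarray(self.B, float))
        self.beta_Y = np.asarray(self.beta_Y, float)
        self.var_Y = np.asarray(self.var_Y, float)
        self.C = np.asarray(self.C, float)
        m, ncol = self.B.shape
        if ncol != len(self.mediator_ids) + 1:
            raise ValueError("B must have k+1 columns")
        if len(self.beta_Y) != m or self.C.shape != (m, m):
            raise ValueError("row count mismatch between B, beta_Y and C")

    @property
    def m(self) -> int:
        return self.B.shape[0]

    @property
    def k(self) -> int:
        return len(self.mediator_ids)

    @property
    def n_exposure_ivs(self) -> int:
        return int(np.sum(self.B[:, 0] != 0))


def rank_score_clump(exposure_ivs: list[str],
                     mediator_iv_stats: dict[str, SummaryStatsTable],
                     ld: LDPanel, r2_thresh: float = 0.05) -> list[str]:
    """Pool exposure and mediator instruments with rank-score clumping.

    Exposure IVs are kept unconditionally (they are already mutually
    clumped). Mediator-associated IVs are ordered by the sum over
    mediators of their within-mediator p-value ranks (1 = strongest), ties
    broken by the IV's minimum p-value then position, and greedily clumped
    at ``r2_thresh`` against everything already kept.
    """
    ranks: dict[str, float] = {}
    min_p: dict[str, float] = {}
    pos: dict[str, float] = {}
    for stats_k in mediator_iv_stats.values():
        df = stats_k.df.sort_values(["pvalue", "pos"], kind="mergesort")
        for rank, row in enumerate(df.itertuples(), start=1):
            vid = row.variant_id
            ranks[vid] = ranks.get(vid, 0) + rank
            min_p[vid] = min(min_p.get(vid, np.inf), row.pvalue)
            pos[vid] = row.pos
    pooled = list(exposure_ivs)
    order = sorted(ranks, key=lambda v: (ranks[v], min_p[v], pos[v]))
    for vid in order:
        if vid in pooled:
            continue
        if not pooled:
            pooled.append(vid)
            continue
        r = ld.cross_matrix([vid], pooled)[0]
        if np.max(r ** 2) < r2_thresh:
            pooled.append(vid)
    return pooled


def build_design_matrix(exposure_stats: SummaryStatsTable,
                        mediator_stats: dict[str, SummaryStatsTable],
                        outcome_stats: SummaryStatsTable,
                        pooled_ivs: list[str], ld: LDPanel,
                        pair_id: str = "pair") -> MVMRProblem:
    """Fill B with reported standardized effects; absent entries become 0.

    The outcome table is assumed complete: pooled IVs missing from it are
    dropped with a warning.
    """
    out_idx = outcome_stats.df.set_index("variant_id")
    ivs = [v for v in pooled_ivs if v in out_idx.index]
    missing = len(pooled_ivs) - len(ivs)
    if missing:
        log.warning("%s: dropped %d pooled IVs missing from the outcome table",
                    pair_id, missing)
    mediator_ids = list(mediator_stats)
    B = np.zeros((len(ivs), 1 + len(mediator_ids)))
    tables = [exposure_stats] + [mediator_stats[mid] for mid in mediator_ids]
    for col, tab in enumerate(tables):
        tab_idx = tab.df.set_index("variant_id")["beta"]
        for row, vid in enumerate(ivs):
            if vid in tab_idx.index:
                B[row, col] = tab_idx[vid]
    beta_Y = out_idx.loc[ivs, "beta"].to_numpy(float)
    var_Y = out_idx.loc[ivs, "se"].to_numpy(float) ** 2
    return MVMRProblem(pair_id, ivs, B, beta_Y, var_Y, ld.submatrix(ivs),
                       mediator_ids)


def _independent_columns(W: np.ndarray, tol: float = COLLINEARITY_TOL):
    """Greedy rank-revealing selection keeping column 0 unconditionally."""
    keep = [0]
    basis = W[:, [0]] / max(np.linalg.norm(W[:, 0]), tol)
    for j in range(1, W.shape[1]):
        col = W[:, j]
        resid = col - basis @ (basis.T @ col)
        if np.linalg.norm(resid) > tol * max(np.linalg.norm(col), 1.0):
            keep.append(j)
            q = resid / np.linalg.norm(resid)
            basis = np.column_stack([basis, q])
    return keep


class MVMRModel:
    """Multivariable MR model for one exposure-outcome pair."""

    def __init__(self, problem: MVMRProblem,
                 min_exposure_ivs: int = 3):
        if problem.m < problem.k + 1:
            raise ValueError("need at least k+1 instruments")
        if problem.n_exposure_ivs < min_exposure_ivs:
            raise UntestablePairError(
                f"{problem.pair_id}: only {problem.n_exposure_ivs} exposure "
                f"IVs (< {min_exposure_ivs}); pair untestable")
        self.problem = problem

    def fit(self) -> "MVMRResults":
        prob = self.problem
        Cinv = regularized_inverse(prob.C)
        Cmh = inverse_sqrt(prob.C)
        W = Cmh @ prob.B
        keep = _independent_columns(W)
        dropped = [prob.mediator_ids[j - 1]
                   for j in range(1, prob.B.shape[1]) if j not in keep]
        if dropped:
            log.warning("%s: dropped collinear mediator columns: %s",
                        prob.pair_id, dropped)
        B = prob.B[:, keep]
        mediator_ids = [prob.mediator_ids[j - 1] for j in keep[1:]]
        m, ncol = B.shape
        k = ncol - 1
        A = B.T @ Cinv @ B
        Ainv = np.linalg.inv(A)
        theta_vec = Ainv @ (B.T @ Cinv @ prob.beta_Y)
        resid = prob.beta_Y - B @ theta_vec
        dof = max(m - ncol, 1)
        s2 = float(resid @ Cinv @ resid) / dof
        sigma_diag = np.maximum(s2, prob.var_Y)
        WB = Cmh @ B
        cov = Ainv @ (WB.T * sigma_diag) @ WB @ Ainv
        se_vec = np.sqrt(np.diag(cov))
        theta_D = float(theta_vec[0])
        se_D = float(se_vec[0])
        tiny = float(np.finfo(float).tiny)
        p_D = (max(float(2 * stats.norm.sf(abs(theta_D / se_D))), tiny)
               if se_D > 0 else tiny)
        alpha_MY = {mid: (float(theta_vec[j + 1]), float(se_vec[j + 1]))
                    for j, mid in enumerate(mediator_ids)}
        return MVMRResults(self, theta_D=theta_D, se_D=se_D, p_D=p_D,
                           theta_vec=theta_vec, cov=cov,
                           alpha_MY=alpha_MY, mediator_ids=mediator_ids,
                           dropped_mediators=dropped, s2=s2,
                           sigma_diag=sigma_diag, _Cinv=Cinv, _Cmh=Cmh, _B=B)


@dataclass
class MVMRResults:
    """Direct-effect estimates and diagnostics from :meth:`MVMRModel.fit`."""

    model: MVMRModel
    theta_D: float
    se_D: float
    p_D: float
    theta_vec: np.ndarray
    cov: np.ndarray
    alpha_MY: dict[str, tuple[float, float]]
    mediator_ids: list[str]
    dropped_mediators: list[str]
    s2: float
    sigma_diag: np.ndarray
    _Cinv: np.ndarray
    _Cmh: np.ndarray
    _B: np.ndarray

    @property
    def m(self) -> int:
        return self._B.shape[0]

    @property
    def k(self) -> int:
        return self._B.shape[1] - 1

    def q_statistic(self) -> tuple[float, int, float]:
        """Heterogeneity Q on decorrelated residuals, df = m - k."""
        if self.m <= self.k:
            raise ValueError("Q undefined when m <= k")
        prob = self.model.problem
        u = self._Cmh @ (prob.beta_Y - self._B @ self.theta_vec)
        Q = float(np.sum(u ** 2 / self.sigma_diag))
        df = self.m - self.k
        return Q, df, float(stats.chi2.sf(Q, df))

    def conditional_f(self, n_E: float, n_M: float | None = None,
                      pheno_corr: np.ndarray | None = None) -> float:
        return conditional_f(self.model.problem, n_E, n_M=n_M,
                             pheno_corr=pheno_corr)

    def summary(self) -> str:
        prob = self.model.problem
        lines = [
            "Multivariable MR (correlated instruments)",
            f"  pair:          {prob.pair_id}",
            f"  instruments:   {self.m} ({prob.n_exposure_ivs} exposure)",
            f"  mediators:     {self.k}",
            f"  theta_D:       {self.theta_D:.6g}",
            f"  se(theta_D):   {self.se_D:.6g}",
            f"  p(theta_D):    {self.p_D:.3g}",
        ]
        for mid, (a, s) in self.alpha_MY.items():
            lines.append(f"  alpha_MY[{mid}]: {a:.6g} (se {s:.6g})")
        if self.m > self.k:
            Q, df, p = self.q_statistic()
            lines.append(f"  Q:             {Q:.4g} (df={df}, p={p:.3g})")
        return "\n".join(lines)


def conditional_f(prob: MVMRProblem, n_E: float, n_M: float | None = None,
                  pheno_corr: np.ndarray | None = None) -> float:
    """Sanderson-style conditional F-statistic of the exposure.

    The exposure IV-effect column is regressed (C^-1-weighted) on the
    mediator columns; the residual instrument strength is

        F_cond = e' C^-1 e / ((m - k) * sigma_v^2)

    with sigma_v^2 = 1/n_E + delta' R delta / n_M the sampling variance of
    the residual effects on the standardized scale, R the mediator
    phenotypic correlation matrix (identity when not supplied, the default)
    and delta the regression coefficients. With no mediators this is the
    standard mean F-statistic of the exposure instruments, n_E b'C^-1 b/m.
    Values above 10 indicate the exposure instruments remain strong
    conditional on the mediators.
    """
    m, k = prob.m, prob.k
    if m <= k:
        raise ValueError("conditional F undefined when m <= k")
    if n_M is None:
        n_M = n_E
    Cinv = regularized_inverse(prob.C)
    x = prob.B[:, 0]
    if k == 0:
        e = x
        delta = np.zeros(0)
    else:
        Z = prob.B[:, 1:]
        G = Z.T @ Cinv @ Z
        delta, *_ = np.linalg.lstsq(G, Z.T @ Cinv @ x, rcond=None)
        e = x - Z @ delta
    R = np.eye(k) if pheno_corr is None else np.asarray(pheno_corr, float)
    sigma_v2 = 1.0 / n_E + float(delta @ R @ delta) / n_M if k else 1.0 / n_E
    return float(e @ Cinv @ e) / ((m - k) * sigma_v2)
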