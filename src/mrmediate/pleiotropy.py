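"""By-chance-LD horizontal-pleiotropy null simulation for
exposure-transcript MR.

Cis mQTL and eQTL signals live in the same genomic neighbourhood, so a
significant exposure->transcript MR effect could in principle arise purely
from LD between the two sets of instruments. The null simulation keeps the
transcript's multivariable eQTL effect-size distribution fixed but
reassigns it to randomly drawn SNPs in the region: for each replicate j,

    beta_multi    = C_M^-1 beta_M             (multivariable eQTL effects)
    beta_marg,j   = C_{E,M_j} beta_multi      (implied marginal effects at
                                               the exposure IVs)

and the exposure->hypothetical-transcript MR is re-run with beta_marg,j as
the outcome vector. The simulation p-value is the fraction of null
replicates whose MR p-value beats the real pair's.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._linalg import regularized_inverse
from .io import LDPanel
from .ivw import InstrumentSet, IVWModel


@dataclass
class PleiotropySimConfig:
    """Settings for the null simulation.

    ``n_sim`` defaults to a desk-scale 1,000 replicates; the full-scale
    analysis uses 100,000. The random SNP pool is pruned once at
    ``r2_pool`` (lenient, 0.5) by position-ordered traversal and sampled
    uniformly without replacement per replicate.
    """

    n_sim: int = 1_000
    r2_pool: float = 0.5
    seed: int | None = None

    def __post_init__(self):
        if self.n_sim < 1:
            raise ValueError("n_sim must be >= 1")


@dataclass
class PleiotropySimResult:
    pair_id: str
    n_sim: int
    p_sim: float
    real_p_em: float
    null_p_values: np.ndarray | None = None

    def to_row(self) -> dict:
        return {"pair_id": self.pair_id, "n_sim": self.n_sim,
                "p_sim": self.p_sim, "real_p_EM": self.real_p_em}


def multivariable_effects(beta_M: np.ndarray, C_M: np.ndarray) -> np.ndarray:
    """Multivariable (joint) SNP effects implied by marginal effects and
    their LD matrix: beta_multi = C_M^-1 beta_M."""
    beta_M = np.asarray(beta_M, float)
    C_M = np.asarray(C_M, float)
    if C_M.shape != (len(beta_M), len(beta_M)):
        raise ValueError("C_M must be square and match beta_M")
    return regularized_inverse(C_M) @ beta_M


def marginalize(beta_multi: np.ndarray, C_cross: np.ndarray) -> np.ndarray:
    """Marginal effects at the exposure IVs implied by multivariable
    effects at another SNP set: beta_marginal = C_cross beta_multi."""
    beta_multi = np.asarray(beta_multi, float)
    C_cross = np.atleast_2d(np.asarray(C_cross, float))
    if C_cross.shape[1] != len(beta_multi):
        raise ValueError("C_cross columns must match beta_multi length")
    return C_cross @ beta_multi


def prune_pool(ld: LDPanel, r2_thresh: float = 0.5,
               exclude: set[str] | None = None) -> list[str]:
    """Greedy position-ordered pruning of the panel at ``r2_thresh``."""
    exclude = exclude or set()
    order = ld.index.sort_values("pos")["variant_id"].tolist()
    kept: list[str] = []
    for vid in order:
        if vid in exclude:
            continue
        if not kept:
            kept.append(vid)
            continue
        r = ld.cross_matrix([vid], kept)[0]
        if np.max(r ** 2) < r2_thresh:
            kept.append(vid)
    return kept


def run_pleiotropy_sim(exposure_ivs: list[str], beta_E: np.ndarray,
                       var_E: np.ndarray, mediator_ivs: list[str],
                       beta_M: np.ndarray, var_M: np.ndarray,
                       real_p_em: float, ld: LDPanel,
                       cfg: PleiotropySimConfig | None = None,
                       keep_null_p: bool = False) -> PleiotropySimResult:
    """Null distribution of exposure->transcript MR p-values under random
    placement of the transcript's multivariable eQTL effects.

    ``exposure_ivs``/``beta_E`` are the real pair's exposure instruments
    and effects; ``mediator_ivs``/``beta_M`` the transcript's instruments
    and marginal eQTL effects. The mediator effect variance of the
    hypothetical transcript keeps the real pair's values for
    comparability.
    """
    cfg = cfg or PleiotropySimConfig()
    m_M = len(mediator_ivs)
    beta_multi = multivariable_effects(beta_M, ld.submatrix(mediator_ivs))
    pool = prune_pool(ld, cfg.r2_pool)
    if len(pool) < m_M:
        raise ValueError(f"pruned pool ({len(pool)}) smaller than m_M ({m_M})")
    rng = np.random.default_rng(cfg.seed)
    C_E = ld.submatrix(exposure_ivs)
    # eQTL sampling variance of the hypothetical transcript at the
    # exposure IVs: the real pair's typical per-SNP variance
    var_null = np.full(len(exposure_ivs), float(np.median(var_M)))
    null_p = np.empty(cfg.n_sim)
    for j in range(cfg.n_sim):
        draw = list(rng.choice(pool, size=m_M, replace=False))
        C_cross = ld.cross_matrix(exposure_ivs, draw)
        b_marg = marginalize(beta_multi, C_cross)
        res = IVWModel(InstrumentSet(
            f"null{j}", list(exposure_ivs), beta_E, var_E,
            b_marg, var_null, C_E)).fit()
        null_p[j] = res.pvalue
    p_sim = float(np.sum(null_p < real_p_em)) / cfg.n_sim
    return PleiotropySimResult(
        "|".join([exposure_ivs[0], mediator_ivs[0]]), cfg.n_sim, p_sim,
        real_p_em, null_p if keep_null_p else None)
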