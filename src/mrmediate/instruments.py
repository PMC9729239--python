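"""Instrument selection: cis-window p-value filtering, greedy r2 clumping,
Steiger directionality filtering and distance clumping."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io import LDPanel, SummaryStatsTable


@dataclass
class SteigerConfig:
    """Directionality-filter threshold.

    An instrument passes when t = (|b_X| - |b_Z|) / sqrt(var_X + var_Z)
    exceeds ``t_rev``; the default -2 corresponds to a one-sided normal
    p-value of about 0.023.
    """

    t_rev: float = -2.0

    def __post_init__(self):
        if not np.isfinite(self.t_rev):
            raise ValueError("t_rev must be finite")

    @property
    def one_sided_p(self) -> float:
        """One-sided p-value equivalent of the threshold."""
        return float(stats.norm.cdf(self.t_rev))


def steiger_filter(beta_X, var_X, beta_Z, var_Z,
                   cfg: SteigerConfig | None = None) -> np.ndarray:
    """Boolean mask of instruments whose downstream (Z) effect is not
    credibly larger than their upstream (X) effect.

    Guards against reverse causation: an IV with a much larger effect on
    the downstream trait is likely acting on it directly.
    """
    cfg = cfg or SteigerConfig()
    beta_X, var_X = np.asarray(beta_X, float), np.asarray(var_X, float)
    beta_Z, var_Z = np.asarray(beta_Z, float), np.asarray(var_Z, float)
    if beta_X.shape != beta_Z.shape:
        raise ValueError("effect vectors must have equal length")
    if (var_X <= 0).any() or (var_Z <= 0).any():
        raise ValueError("variances must be positive")
    t = (np.abs(beta_X) - np.abs(beta_Z)) / np.sqrt(var_X + var_Z)
    return t > cfg.t_rev


def select_instruments(stats_table: SummaryStatsTable, ld: LDPanel,
                       p_thresh: float = 1e-6, r2_thresh: float = 0.05,
                       window: tuple[int, int] | None = None) -> list[str]:
    """Greedy p-value-ordered selection of near-independent instruments.

    Variants inside ``window`` (1-based inclusive) with p < ``p_thresh``
    are visited by ascending p-value; a variant is kept iff its squared
    correlation with every already-kept variant is below ``r2_thresh``.
    """
    df = stats_table.df
    in_panel = df["variant_id"].isin(set(ld.variant_ids))
    mask = in_panel & (df["pvalue"] < p_thresh)
    if window is not None:
        lo, hi = window
        mask &= df["pos"].between(lo, hi)
    cand = df[mask].sort_values(["pvalue", "pos"], kind="mergesort")
    kept: list[str] = []
    for vid in cand["variant_id"]:
        if not kept:
            kept.append(vid)
            continue
        r = ld.cross_matrix([vid], kept)[0]
        if np.max(r ** 2) < r2_thresh:
            kept.append(vid)
    return kept


def distance_clump(ids, positions, pvalues, distance: int = 1_000_000) -> list:
    """Greedy distance clumping: visit by ascending p (ties by position),
    drop anything within ``distance`` bp of an already-kept entry."""
    order = sorted(range(len(ids)), key=lambda i: (pvalues[i], positions[i]))
    kept_idx: list[int] = []
    for i in order:
        if all(abs(positions[i] - positions[j]) > distance for j in kept_idx):
            kept_idx.append(i)
    kept = set(kept_idx)
    return [ids[i] for i in range(len(ids)) if i in kept]
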