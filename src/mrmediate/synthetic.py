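"""File-level synthetic fixtures: an LD panel plus mQTL-, eQTL- and
GWAS-style summary tables for cis regions with known ground truth.

A region is simulated at the level of causal effect vectors: exposure
causal SNPs cluster around the methylation probe, each transcript's
direct causal SNPs cluster around its TSS, and marginal (single-SNP)
effects are obtained by multiplying causal vectors with an AR(1) LD
matrix (element (i,j) = decay^|i-j|, positive definite by construction).
Sampling noise at the stated sample sizes is added, and each table is
written with its reporting threshold applied (the mQTL table keeps only
P < 1e-6 rows, mimicking significant-only cis-mQTL releases; the eQTL
table keeps rows at an FDR-equivalent threshold), which exercises the
downstream rule that unreported design-matrix entries are exact zeros.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .io import LDPanel, SummaryStatsTable, write_ld_panel
from scipy import stats as _stats


@dataclass
class TranscriptBlueprint:
    """One cis transcript: its TSS and true causal-chain effects."""

    transcript_id: str
    tss: int
    alpha_EM: float          # true exposure -> transcript effect
    alpha_MY: float          # true transcript -> outcome effect
    h2_direct: float = 0.05  # direct (non-exposure) cis-heritability
    m_M: int = 5             # direct causal SNPs


@dataclass
class RegionBlueprint:
    """Blueprint of one cis region around a methylation probe."""

    region_id: str
    chrom: int = 1
    n_snps: int = 420
    ld_decay: float = 0.9
    maf_range: tuple[float, float] = (0.05, 0.5)
    pos_start: int = 1_000_000
    spacing: int = 2_000
    probe_offset: int = 120          # probe sits at this SNP index
    m_E: int = 8                     # exposure causal SNPs
    h2_E: float = 0.15
    theta_D: float = 0.05            # true direct exposure->outcome effect
    transcripts: list[TranscriptBlueprint] = field(default_factory=list)
    n_exposure: int = 32_851
    n_mediator: int = 31_684
    n_outcome: int = 300_000
    mqtl_report_p: float = 1e-6
    eqtl_report_p: float = 1.8e-5
    af_perturb: float = 0.0          # optional AF shift of the GWAS table
    palindromic_fraction: float = 0.0

    def __post_init__(self):
        if not (0 <= self.ld_decay < 1):
            raise ValueError("ld_decay must lie in [0, 1)")
        if self.n_snps < 2:
            raise ValueError("need at least 2 SNPs")

    @property
    def probe_pos(self) -> int:
        return self.pos_start + self.probe_offset * self.spacing

    @property
    def theta_M(self) -> float:
        return float(sum(t.alpha_EM * t.alpha_MY for t in self.transcripts))

    @property
    def theta_T(self) -> float:
        return self.theta_D + self.theta_M

    @property
    def true_mp(self) -> float:
        return self.theta_M / self.theta_T if self.theta_T else np.nan


def generate_ld_panel(blueprint: RegionBlueprint,
                      seed: int | None = None) -> LDPanel:
    """AR(1) LD panel on a position grid: r(i,j) = decay^|i-j|."""
    rng = np.random.default_rng(seed)
    n = blueprint.n_snps
    idx = np.arange(n)
    R = blueprint.ld_decay ** np.abs(idx[:, None] - idx[None, :])
    alleles = np.array([("A", "G"), ("C", "T"), ("G", "A"), ("T", "C")])
    pick = rng.integers(0, len(alleles), n)
    a1 = alleles[pick, 0].copy()
    a2 = alleles[pick, 1].copy()
    if blueprint.palindromic_fraction > 0:
        n_pal = int(round(blueprint.palindromic_fraction * n))
        pal_idx = rng.choice(n, n_pal, replace=False)
        a1[pal_idx], a2[pal_idx] = "A", "T"
    index = pd.DataFrame({
        "variant_id": [f"{blueprint.region_id}_snp{i}" for i in idx],
        "chrom": blueprint.chrom,
        "pos": blueprint.pos_start + idx * blueprint.spacing,
        "a1": a1, "a2": a2})
    return LDPanel(index, R)


def _rescaled(rng, scale2, size):
    b = rng.normal(0.0, np.sqrt(scale2 / size), size)
    return b * np.sqrt(scale2 / np.sum(b ** 2))


def _table(panel: LDPanel, beta_hat: np.ndarray, se: float, eaf: np.ndarray,
           n: int, trait_id: str, role: str,
           report_p: float | None) -> SummaryStatsTable:
    z = beta_hat / se
    p = 2 * _stats.norm.sf(np.abs(z))
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    df = pd.DataFrame({
        "variant_id": panel.variant_ids,
        "chrom": panel.index["chrom"].to_numpy(),
        "pos": panel.index["pos"].to_numpy(),
        "ea": panel.index["a1"].to_numpy(),
        "oa": panel.index["a2"].to_numpy(),
        "eaf": eaf, "beta": beta_hat, "se": se, "pvalue": p, "n": n})
    if report_p is not None:
        df = df[df["pvalue"] < report_p].reset_index(drop=True)
    return SummaryStatsTable(trait_id, role, df, n)


def generate_region_fixture(blueprint: RegionBlueprint,
                            seed: int | None = None,
                            outdir: str | Path | None = None):
    """Simulate one region and optionally write its file set.

    Returns ``(ld_panel, mqtl_table, eqtl_tables, gwas_table, truth)``
    where ``eqtl_tables`` maps transcript_id -> (table, tss) and ``truth``
    is a plain dict (also written as truth.yaml when ``outdir`` is set).
    """
    rng = np.random.default_rng(seed)
    bp = blueprint
    panel = generate_ld_panel(bp, seed)
    n = bp.n_snps
    C = panel.R

    # exposure causal SNPs spread around the probe widely enough that
    # r2 < 0.05 pruning can retain them as separate instruments
    lo = max(0, bp.probe_offset - 60)
    hi = min(n, bp.probe_offset + 60)
    exp_idx = rng.choice(np.arange(lo, hi), size=bp.m_E, replace=False)
    beta_Ec = np.zeros(n)
    beta_Ec[exp_idx] = _rescaled(rng, bp.h2_E, bp.m_E)

    # transcript direct-causal SNPs cluster tightly at the TSS; keeping
    # them clear of the exposure cluster avoids LD-driven pleiotropy in
    # the exposure->transcript MR except where a blueprint asks for it
    beta_Mc = {}
    for t in bp.transcripts:
        tss_idx = int(round((t.tss - bp.pos_start) / bp.spacing))
        tlo = max(0, min(tss_idx - 15, n - t.m_M))
        thi = min(n, max(tss_idx + 15, t.m_M))
        own = rng.choice(np.arange(tlo, thi), size=t.m_M, replace=False)
        bc = t.alpha_EM * beta_Ec
        bc[own] = bc[own] + _rescaled(rng, t.h2_direct, t.m_M)
        beta_Mc[t.transcript_id] = bc

    beta_Yc = bp.theta_D * beta_Ec
    for t in bp.transcripts:
        beta_Yc = beta_Yc + t.alpha_MY * beta_Mc[t.transcript_id]

    eaf = rng.uniform(*bp.maf_range, n)
    se_E = 1.0 / np.sqrt(bp.n_exposure)
    se_M = 1.0 / np.sqrt(bp.n_mediator)
    se_Y = 1.0 / np.sqrt(bp.n_outcome)

    mqtl = _table(panel, C @ beta_Ec + rng.normal(0, se_E, n), se_E, eaf,
                  bp.n_exposure, f"{bp.region_id}_probe", "exposure",
                  bp.mqtl_report_p)
    eqtl: dict[str, tuple[SummaryStatsTable, int]] = {}
    for t in bp.transcripts:
        tab = _table(panel, C @ beta_Mc[t.transcript_id]
                     + rng.normal(0, se_M, n), se_M, eaf,
                     bp.n_mediator, t.transcript_id, "mediator",
                     bp.eqtl_report_p)
        eqtl[t.transcript_id] = (tab, t.tss)
    gwas_eaf = np.clip(eaf + bp.af_perturb, 0.0, 1.0)
    gwas = _table(panel, C @ beta_Yc + rng.normal(0, se_Y, n), se_Y,
                  gwas_eaf, bp.n_outcome, "outcome", "outcome", None)

    truth = {
        "region_id": bp.region_id,
        "probe_id": mqtl.trait_id,
        "probe_pos": int(bp.probe_pos),
        "theta_T": float(bp.theta_T),
        "theta_D": float(bp.theta_D),
        "theta_M": float(bp.theta_M),
        "true_mp": float(bp.true_mp),
        "mediators": {t.transcript_id: {"alpha_EM": float(t.alpha_EM),
                                        "alpha_MY": float(t.alpha_MY),
                                        "tss": int(t.tss)}
                      for t in bp.transcripts},
    }

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_ld_panel(panel, outdir / "ld.tsv", outdir / "ld_index.tsv")
        mqtl.df.to_csv(outdir / "mqtl.tsv", sep="\t", index=False)
        rows = []
        for tid, (tab, tss) in eqtl.items():
            d = tab.df.copy()
            d.insert(0, "phenotype_id", tid)
            d["tss"] = tss
            rows.append(d)
        if rows:
            pd.concat(rows).to_csv(outdir / "eqtl.tsv", sep="\t", index=False)
        else:
            cols = ["phenotype_id"] + list(mqtl.df.columns) + ["tss"]
            pd.DataFrame(columns=cols).to_csv(outdir / "eqtl.tsv", sep="\t",
                                              index=False)
        gwas.df.to_csv(outdir / "gwas.tsv", sep="\t", index=False)
        with open(outdir / "truth.yaml", "w") as fh:
            yaml.safe_dump(truth, fh, sort_keys=False)

    return panel, mqtl, eqtl, gwas, truth


def cohort_blueprints(n_regions: int = 30, seed: int | None = None,
                      frac_no_transcript: float = 0.1,
                      frac_null_mediation: float = 0.2) -> list[RegionBlueprint]:
    """A mixed cohort: regions with active mediation (varied true MPs),
    regions whose transcripts are causally unlinked to the probe
    (non-detectable mediation) and regions without any cis transcript."""
    rng = np.random.default_rng(seed)
    bps = []
    n_none = int(round(frac_no_transcript * n_regions))
    n_null = int(round(frac_null_mediation * n_regions))
    for i in range(n_regions):
        rid = f"r{i:02d}"
        chrom = (i % 22) + 1
        pos_start = 1_000_000 + (i // 22) * 50_000_000
        kind = ("none" if i < n_none
                else "null" if i < n_none + n_null else "active")
        transcripts = []
        if kind != "none":
            n_tr = int(rng.integers(1, 4))
            for j in range(n_tr):
                tss = pos_start + int(rng.integers(230, 360)) * 2_000
                if kind == "null":
                    a_em, a_my = 0.0, float(rng.normal(0, 0.1))
                else:
                    a_em = float(rng.choice([-1, 1]) * rng.uniform(0.3, 0.7))
                    a_my = float(rng.choice([-1, 1]) * rng.uniform(0.03, 0.12))
                transcripts.append(TranscriptBlueprint(
                    f"{rid}_tr{j}", tss, a_em, a_my))
        # the direct effect shares the mediated path's sign so total
        # effects stay clearly nonzero and pass the screening gate
        theta_M = sum(t.alpha_EM * t.alpha_MY for t in transcripts)
        sign = np.sign(theta_M) if theta_M else rng.choice([-1, 1])
        theta_D = float(sign * rng.uniform(0.04, 0.1))
        bps.append(RegionBlueprint(
            rid, chrom=chrom, pos_start=pos_start, theta_D=theta_D,
            transcripts=transcripts))
    return bps


def generate_cohort(blueprints: list[RegionBlueprint], seed: int | None = None,
                    outdir: str | Path | None = None) -> list[dict]:
    """Generate every region of a cohort (one subdirectory per region when
    writing); returns the list of truth records."""
    truths = []
    ss = np.random.SeedSequence(seed).spawn(len(blueprints))
    for bp, s in zip(blueprints, ss):
        sub = None if outdir is None else Path(outdir) / bp.region_id
        rng_seed = int(s.generate_state(1)[0] % (2 ** 31))
        *_, truth = generate_region_fixture(bp, rng_seed, sub)
        truths.append(truth)
    return truths
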