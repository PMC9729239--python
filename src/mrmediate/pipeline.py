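"""Genome-wide screening pipeline: probe screening, total-effect
estimation, distance clumping, per-pair mediation, MP aggregation and the
sensitivity suites, driven by a single config.

Inputs are per-region file sets (mQTL table, long-format eQTL table, GWAS
table, LD matrix + variant index) listed in a regions manifest. Stage
counts mirroring the screening flowchart are recorded in a run manifest
together with a config hash and the seed, so a rerun with the same config
is verifiably identical.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .instruments import distance_clump, select_instruments
from .io import (LDPanel, SummaryStatsTable, read_ld_panel,
                 read_multi_trait_stats, read_summary_stats)
from .ivw import InstrumentSet, IVWModel
from .mediation import (MediationConfig, PairResult, estimate_mp,
                        mediate_pair, pairs_to_table, select_mediators)

log = logging.getLogger(__name__)

_PALINDROMIC = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


@dataclass
class RegionInput:
    """Paths and probe metadata for one cis region."""

    region_id: str
    mqtl: str
    eqtl: str
    gwas: str
    ld_matrix: str
    ld_index: str
    probe_pos: int
    probe_id: str | None = None


@dataclass
class ScreenConfig:
    """Configuration of one screening run."""

    regions: list[RegionInput]
    p_T_thresh: float = 1e-6            # Bonferroni 0.05/50,000
    clump_distance: int = 1_000_000
    min_pairs: int = 10
    variant_modes: tuple[str, ...] = ()
    mediation: MediationConfig = field(default_factory=MediationConfig)
    trait_categories: dict[str, str] = field(default_factory=dict)
    seed: int | None = None
    output_dir: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "ScreenConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        regions = [RegionInput(**r) for r in raw.pop("regions")]
        med = MediationConfig(**raw.pop("mediation", {}))
        return cls(regions=regions, mediation=med, **raw)

    def config_hash(self) -> str:
        payload = yaml.safe_dump({
            "regions": [vars(r) for r in self.regions],
            "p_T_thresh": self.p_T_thresh,
            "clump_distance": self.clump_distance,
            "min_pairs": self.min_pairs,
            "variant_modes": list(self.variant_modes),
            "mediation": {k: v for k, v in vars(self.mediation).items()
                          if not hasattr(v, "__dict__")},
            "seed": self.seed}, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def align_to_panel(table: SummaryStatsTable, ld: LDPanel,
                   af_tol: float = 0.05,
                   af_reference: dict[str, float] | None = None
                   ) -> SummaryStatsTable:
    """Orient one table to the LD panel's allele coding.

    Keeps autosomal variants present in the panel, flips effect signs and
    AFs where effect/other alleles are swapped relative to the panel,
    drops palindromic variants and allele-set mismatches, and (when a
    reference AF map is given) drops variants whose oriented AF differs
    from the reference by more than ``af_tol``.
    """
    idx = ld.index.set_index("variant_id")
    df = table.df[table.df["chrom"].between(1, 22)].copy()
    df = df[df["variant_id"].isin(idx.index)]
    if df.empty:
        return replace(table, df=df.reset_index(drop=True))
    a1 = idx.loc[df["variant_id"], "a1"].to_numpy()
    a2 = idx.loc[df["variant_id"], "a2"].to_numpy()
    match = (df["ea"].to_numpy() == a1) & (df["oa"].to_numpy() == a2)
    swap = (df["ea"].to_numpy() == a2) & (df["oa"].to_numpy() == a1)
    df = df[match | swap].copy()
    sw = swap[match | swap]
    df.loc[sw, "beta"] = -df.loc[sw, "beta"]
    df.loc[sw, "eaf"] = 1.0 - df.loc[sw, "eaf"]
    df.loc[sw, ["ea", "oa"]] = df.loc[sw, ["oa", "ea"]].to_numpy()
    pal = np.array([(a, b) in _PALINDROMIC
                    for a, b in zip(df["ea"], df["oa"])])
    df = df[~pal]
    if af_reference:
        ref = df["variant_id"].map(af_reference)
        keep = ref.isna() | df["eaf"].isna() | ((df["eaf"] - ref).abs() <= af_tol)
        df = df[keep]
    return replace(table, df=df.reset_index(drop=True))


def load_region(region: RegionInput):
    """Read and panel-align one region's tables."""
    ld = read_ld_panel(region.ld_matrix, region.ld_index)
    mqtl = read_summary_stats(region.mqtl,
                              region.probe_id or f"{region.region_id}_probe",
                              "exposure")
    gwas = read_summary_stats(region.gwas, "outcome", "outcome")
    gwas = align_to_panel(gwas, ld)
    af_ref = dict(zip(gwas.df["variant_id"], gwas.df["eaf"]))
    mqtl = align_to_panel(mqtl, ld, af_reference=af_ref)
    raw = pd.read_csv(region.eqtl, sep="\t")
    transcripts: dict[str, tuple[SummaryStatsTable, int]] = {}
    if len(raw):
        tss_map = raw.groupby("phenotype_id")["tss"].first().to_dict()
        tabs = read_multi_trait_stats(region.eqtl, "mediator")
        for tid, tab in tabs.items():
            transcripts[tid] = (align_to_panel(tab, ld, af_reference=af_ref),
                                int(tss_map[tid]))
    return ld, mqtl, transcripts, gwas


@dataclass
class ScreenResult:
    """Everything one screening run produced."""

    pairs: list[PairResult]
    variant_pairs: dict[str, list[PairResult]]
    mp_estimates: dict[str, dict]
    sensitivity: dict[str, dict]
    stage_counts: dict[str, int]
    manifest: dict


def _q_ok(q, thresh=0.01):
    return q is None or q[2] > thresh


def run_screen(cfg: ScreenConfig) -> ScreenResult:
    """Run the full screen; writes tables and a manifest when
    ``cfg.output_dir`` is set."""
    med_cfg = cfg.mediation
    stage = {"regions": len(cfg.regions), "ge_min_ivs": 0, "p_T_significant": 0,
             "after_distance_clump": 0, "testable": 0, "no_cis_transcript": 0,
             "non_detectable": 0, "detectable": 0}

    screened = []   # (region, ld, mqtl, transcripts, gwas, ivs, theta_T stats)
    for region in cfg.regions:
        try:
            ld, mqtl, transcripts, gwas = load_region(region)
        except ValueError as err:
            log.warning("%s: unreadable region skipped (%s)",
                        region.region_id, err)
            continue
        window = (region.probe_pos - med_cfg.cis_window_iv,
                  region.probe_pos + med_cfg.cis_window_iv)
        ivs = select_instruments(mqtl, ld, med_cfg.p_iv, med_cfg.r2_iv, window)
        if len(ivs) < med_cfg.min_ivs:
            log.info("%s: %d IVs < %d, excluded", region.region_id,
                     len(ivs), med_cfg.min_ivs)
            continue
        stage["ge_min_ivs"] += 1
        exp_idx = mqtl.df.set_index("variant_id")
        out_idx = gwas.df.set_index("variant_id")
        shared = [v for v in ivs if v in out_idx.index]
        if len(shared) < med_cfg.min_ivs_post_steiger:
            continue
        bE = exp_idx.loc[shared, "beta"].to_numpy(float)
        vE = exp_idx.loc[shared, "se"].to_numpy(float) ** 2
        bY = out_idx.loc[shared, "beta"].to_numpy(float)
        vY = out_idx.loc[shared, "se"].to_numpy(float) ** 2
        uni = IVWModel(InstrumentSet(region.region_id, shared, bE, vE, bY, vY,
                                     ld.submatrix(shared))).fit()
        if uni.pvalue >= cfg.p_T_thresh:
            continue
        stage["p_T_significant"] += 1
        screened.append((region, ld, mqtl, transcripts, gwas, ivs, uni))

    # distance clumping of significant probes by p_T within chromosomes
    kept_ids = set()
    by_chrom: dict[int, list] = {}
    for item in screened:
        chrom = int(item[2].df["chrom"].iloc[0])
        by_chrom.setdefault(chrom, []).append(item)
    for chrom, items in by_chrom.items():
        ids = [it[0].region_id for it in items]
        pos = [it[0].probe_pos for it in items]
        pvals = [it[6].pvalue for it in items]
        kept_ids |= set(distance_clump(ids, pos, pvals, cfg.clump_distance))
    screened = [it for it in screened if it[0].region_id in kept_ids]
    stage["after_distance_clump"] = len(screened)

    pairs: list[PairResult] = []
    variant_pairs: dict[str, list[PairResult]] = {m: [] for m in cfg.variant_modes}
    for region, ld, mqtl, transcripts, gwas, ivs, uni in screened:
        pair = mediate_pair(mqtl, transcripts, gwas, ld, region.probe_pos,
                            med_cfg, exposure_ivs=ivs)
        pairs.append(pair)
        if pair.testable:
            stage["testable"] += 1
            if not pair.has_cis_transcript:
                stage["no_cis_transcript"] += 1
            elif pair.detectable:
                stage["detectable"] += 1
            else:
                stage["non_detectable"] += 1
        for mode in cfg.variant_modes:
            variant_pairs[mode].append(
                mediate_pair(mqtl, transcripts, gwas, ld, region.probe_pos,
                             med_cfg, variant=mode, exposure_ivs=ivs))

    def trait_of(p: PairResult) -> str:
        return p.outcome_id

    def category_of(p: PairResult) -> str:
        return cfg.trait_categories.get(p.outcome_id, "uncategorized")

    mp_estimates: dict[str, dict] = {}
    for mode in ("detectable", "overall"):
        mp_estimates[mode] = {
            "combined": estimate_mp(pairs, None, min_pairs=2, mode=mode),
            "per_trait": estimate_mp(pairs, trait_of,
                                     min_pairs=cfg.min_pairs, mode=mode),
            "per_category": estimate_mp(pairs, category_of, min_pairs=2,
                                        mode=mode)}

    det = [p for p in pairs if p.testable and p.detectable]
    sensitivity = {
        "f_gt10": estimate_mp([p for p in det
                               if p.f_cond is not None and p.f_cond > 10],
                              None, min_pairs=2, mode="detectable"),
        "no_heterogeneity": estimate_mp(
            [p for p in det if _q_ok(p.q_uni) and _q_ok(p.q_mvmr)],
            None, min_pairs=2, mode="detectable")}
    for mode in cfg.variant_modes:
        sensitivity[mode] = estimate_mp(variant_pairs[mode], None,
                                        min_pairs=2, mode="detectable")

    manifest = {"package_version": __version__,
                "config_hash": cfg.config_hash(),
                "seed": cfg.seed,
                "stage_counts": stage}
    result = ScreenResult(pairs, variant_pairs, mp_estimates, sensitivity,
                          stage, manifest)
    if cfg.output_dir:
        _write_outputs(cfg, result)
    return result


def _mp_table(groups: dict) -> pd.DataFrame:
    rows = []
    for key, est in groups.items():
        lo, hi = est.ci95
        rows.append({"group": key, "n_pairs": est.n_pairs,
                     "gamma": est.gamma, "se_gamma": est.se_gamma,
                     "gamma_cor": est.gamma_cor,
                     "se_gamma_cor": est.se_gamma_cor,
                     "mp": est.mp, "ci_lo": lo, "ci_hi": hi})
    return pd.DataFrame(rows)


def _write_outputs(cfg: ScreenConfig, result: ScreenResult) -> None:
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    pairs_to_table(result.pairs).to_csv(out / "pairs.tsv", sep="\t",
                                        index=False)
    for mode, vp in result.variant_pairs.items():
        pairs_to_table(vp).to_csv(out / f"pairs_{mode}.tsv", sep="\t",
                                  index=False)
    for mode, groups in result.mp_estimates.items():
        for level, ests in groups.items():
            _mp_table(ests).to_csv(out / f"mp_{mode}_{level}.tsv", sep="\t",
                                   index=False)
    for name, ests in result.sensitivity.items():
        _mp_table(ests).to_csv(out / f"mp_sensitivity_{name}.tsv", sep="\t",
                               index=False)
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(result.manifest, fh, sort_keys=False)


def run_dnam_transcript_scan(cfg: ScreenConfig) -> pd.DataFrame:
    """All-pairs exposure->transcript MR within the mediator cis window.

    Emits alpha_EM, its SE and p-value for every probe-transcript pair
    with at least the minimum number of Steiger-surviving exposure IVs;
    skipped pairs are counted in the log.
    """
    med_cfg = cfg.mediation
    scan_cfg = replace(med_cfg, p_em=1.01)   # keep every tested pair
    rows = []
    n_skipped = 0
    for region in cfg.regions:
        ld, mqtl, transcripts, _ = load_region(region)
        window = (region.probe_pos - med_cfg.cis_window_iv,
                  region.probe_pos + med_cfg.cis_window_iv)
        ivs = select_instruments(mqtl, ld, med_cfg.p_iv, med_cfg.r2_iv, window)
        if len(ivs) < med_cfg.min_ivs_post_steiger:
            n_skipped += len(transcripts)
            continue
        n_before = len([t for t in transcripts.values()
                        if abs(t[1] - region.probe_pos)
                        <= med_cfg.cis_window_mediators])
        cands = select_mediators(mqtl, ivs, transcripts, ld,
                                 region.probe_pos, scan_cfg)
        n_skipped += n_before - len(cands)
        for c in cands:
            rows.append({"probe_id": mqtl.trait_id,
                         "transcript_id": c.mediator_id,
                         "alpha_EM": c.alpha_EM, "se_EM": c.se_EM,
                         "p_EM": c.p_EM, "n_ivs": c.n_ivs_EM,
                         "tss_distance": c.tss_distance})
    if n_skipped:
        log.info("scan: %d probe-transcript pairs skipped (window or <%d IVs)",
                 n_skipped, med_cfg.min_ivs_post_steiger)
    cols = ["probe_id", "transcript_id", "alpha_EM", "se_EM", "p_EM",
            "n_ivs", "tss_distance"]
    return pd.DataFrame(rows, columns=cols)
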