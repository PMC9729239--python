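"""Shared fixtures: small handcrafted tables and a session-scoped
synthetic cohort on disk."""

import numpy as np
import pandas as pd
import pytest

from mrmediate.io import LDPanel, SummaryStatsTable
from mrmediate.pipeline import RegionInput, ScreenConfig
from mrmediate.synthetic import cohort_blueprints, generate_cohort


def make_table(trait_id, role, variants, n=10_000):
    """Build a SummaryStatsTable from (vid, chrom, pos, ea, oa, eaf, beta,
    se) tuples; p-values derived from z."""
    from scipy import stats
    rows = []
    for vid, chrom, pos, ea, oa, eaf, beta, se in variants:
        p = float(2 * stats.norm.sf(abs(beta / se)))
        rows.append(dict(variant_id=vid, chrom=chrom, pos=pos, ea=ea, oa=oa,
                         eaf=eaf, beta=beta, se=se,
                         pvalue=max(p, np.finfo(float).tiny), n=n))
    return SummaryStatsTable(trait_id, role, pd.DataFrame(rows), n)


def make_panel(variant_ids, R, chrom=1, pos0=1000, spacing=1000,
               alleles=("A", "G")):
    index = pd.DataFrame({
        "variant_id": variant_ids, "chrom": chrom,
        "pos": [pos0 + i * spacing for i in range(len(variant_ids))],
        "a1": alleles[0], "a2": alleles[1]})
    return LDPanel(index, np.asarray(R, float))


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture(scope="session")
def cohort(tmp_path_factory):
    """30-region synthetic cohort written to disk, with its blueprints and
    truth records."""
    outdir = tmp_path_factory.mktemp("cohort")
    bps = cohort_blueprints(30, seed=5)
    truths = generate_cohort(bps, seed=5, outdir=outdir)
    regions = [RegionInput(
        bp.region_id,
        str(outdir / bp.region_id / "mqtl.tsv"),
        str(outdir / bp.region_id / "eqtl.tsv"),
        str(outdir / bp.region_id / "gwas.tsv"),
        str(outdir / bp.region_id / "ld.tsv"),
        str(outdir / bp.region_id / "ld_index.tsv"),
        bp.probe_pos, f"{bp.region_id}_probe") for bp in bps]
    return {"dir": outdir, "blueprints": bps, "truths": truths,
            "config": ScreenConfig(regions=regions, seed=5)}
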