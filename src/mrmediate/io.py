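"""Reading, validation, standardization and harmonization of QTL/GWAS
summary statistics and LD reference matrices.

Tables are held as pandas DataFrames with a canonical column set
(``variant_id, chrom, pos, ea, oa, eaf, beta, se, pvalue, n``) wrapped in a
light :class:`SummaryStatsTable`. Effects are placed on the standardized
(per-SD) scale by dividing z-scores by the square root of the sample size,
so that var(beta) = 1/n throughout the downstream estimators.
"""

from __future__ import annotations

import gzip
import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

CANONICAL_COLUMNS = [
    "variant_id", "chrom", "pos", "ea", "oa", "eaf", "beta", "se", "pvalue", "n",
]

#: Default column-name mapping (GWAS-SSF-like); keys are canonical names,
#: values are accepted aliases in input files.
DEFAULT_DIALECT: Mapping[str, Sequence[str]] = {
    "variant_id": ("variant_id", "rsid", "snp", "id"),
    "chrom": ("chrom", "chromosome", "chr"),
    "pos": ("pos", "base_pair_location", "position", "bp"),
    "ea": ("ea", "effect_allele", "a1"),
    "oa": ("oa", "other_allele", "a2"),
    "eaf": ("eaf", "effect_allele_frequency", "freq"),
    "beta": ("beta", "effect", "b"),
    "se": ("se", "standard_error"),
    "pvalue": ("pvalue", "p_value", "p", "pval"),
    "n": ("n", "sample_size", "nsum"),
    "z": ("z", "zscore", "z_score"),
    "phenotype_id": ("phenotype_id", "gene_id", "probe_id", "trait"),
}

_NUCLEOTIDES = frozenset("ACGT")
_PALINDROMIC = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


@dataclass
class SummaryStatsTable:
    """Per-variant association records for one trait.

    Parameters
    ----------
    trait_id : str
        Identifier of the trait (probe, transcript or outcome).
    trait_role : str
        One of ``exposure``, ``mediator``, ``outcome``.
    df : pandas.DataFrame
        Canonical-column table, one row per variant.
    sample_size_default : int, optional
        Fallback n when a row lacks one.
    """

    trait_id: str
    trait_role: str
    df: pd.DataFrame
    sample_size_default: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.trait_role not in {"exposure", "mediator", "outcome"}:
            raise ValueError(f"unknown trait_role {self.trait_role!r}")
        missing = [c for c in CANONICAL_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"missing canonical columns: {missing}")
        if self.df["variant_id"].duplicated().any():
            raise ValueError("duplicate variant IDs within table")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def variant_ids(self) -> list[str]:
        return self.df["variant_id"].tolist()

    def subset(self, ids: Sequence[str]) -> "SummaryStatsTable":
        """Rows for ``ids`` in the requested order."""
        sub = self.df.set_index("variant_id").loc[list(ids)].reset_index()
        return replace(self, df=sub)

    def lookup(self, ids: Sequence[str], column: str) -> np.ndarray:
        return self.subset(ids).df[column].to_numpy(dtype=float)


@dataclass
class LDPanel:
    """Variant-indexed pairwise correlation matrix.

    ``index`` carries variant_id, chrom, pos (and optionally alleles a1/a2)
    aligned with the rows/columns of ``R``.
    """

    index: pd.DataFrame
    R: np.ndarray

    def __post_init__(self):
        self.R = np.asarray(self.R, dtype=float)
        m = len(self.index)
        if self.R.shape != (m, m):
            raise ValueError("LD matrix shape does not match variant index")
        if not np.allclose(np.diag(self.R), 1.0, atol=1e-8):
            raise ValueError("LD matrix diagonal must be 1")
        if not np.allclose(self.R, self.R.T, atol=1e-10):
            raise ValueError("LD matrix must be symmetric")

    def __len__(self) -> int:
        return len(self.index)

    @property
    def variant_ids(self) -> list[str]:
        return self.index["variant_id"].tolist()

    def positions(self, ids: Sequence[str]) -> np.ndarray:
        return self.index.set_index("variant_id").loc[list(ids), "pos"].to_numpy()

    def submatrix(self, ids: Sequence[str]) -> np.ndarray:
        """LD submatrix in the order of the requested IDs."""
        pos = {v: i for i, v in enumerate(self.index["variant_id"])}
        idx = np.array([pos[v] for v in ids], dtype=int)
        return self.R[np.ix_(idx, idx)]

    def cross_matrix(self, rows: Sequence[str], cols: Sequence[str]) -> np.ndarray:
        pos = {v: i for i, v in enumerate(self.index["variant_id"])}
        ri = np.array([pos[v] for v in rows], dtype=int)
        ci = np.array([pos[v] for v in cols], dtype=int)
        return self.R[np.ix_(ri, ci)]

    def subset(self, ids: Sequence[str]) -> "LDPanel":
        pos = {v: i for i, v in enumerate(self.index["variant_id"])}
        idx = [pos[v] for v in ids]
        return LDPanel(self.index.iloc[idx].reset_index(drop=True),
                       self.R[np.ix_(idx, idx)])


def _open_text(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def _resolve_columns(columns, dialect):
    merged = dict(DEFAULT_DIALECT)
    if dialect:
        for k, v in dialect.items():
            merged[k] = (v,) if isinstance(v, str) else tuple(v)
    lower = {c.lower(): c for c in columns}
    found = {}
    for canon, aliases in merged.items():
        for a in aliases:
            if a.lower() in lower:
                found[canon] = lower[a.lower()]
                break
    return found


def _validate_rows(df: pd.DataFrame, trait_id: str) -> pd.DataFrame:
    """Drop rows violating record invariants, logging the count."""
    n0 = len(df)
    ok = pd.Series(True, index=df.index)
    for col in ("ea", "oa"):
        ok &= df[col].isin(list(_NUCLEOTIDES))
    ok &= df["se"] > 0
    ok &= (df["pvalue"] > 0) & (df["pvalue"] <= 1)
    ok &= df["n"] > 0
    ok &= df["eaf"].isna() | ((df["eaf"] >= 0) & (df["eaf"] <= 1))
    # multi-allelic sites (same ID reported more than once) are dropped
    dup = df["variant_id"].duplicated(keep=False)
    ok &= ~dup
    dropped = n0 - int(ok.sum())
    if dropped:
        log.warning("%s: dropped %d/%d rows failing validation", trait_id, dropped, n0)
    df = df[ok].reset_index(drop=True)
    # soft checks; saturated p-values (underflow near |z| ~ 38) are skipped
    with np.errstate(divide="ignore", invalid="ignore"):
        z = df["beta"] / df["se"]
        z_p = stats.norm.isf(df["pvalue"].to_numpy() / 2.0)
    comparable = np.isfinite(z_p) & (df["pvalue"].to_numpy() > 1e-300)
    bad = comparable & (np.abs(np.abs(z) - z_p) > 0.1)
    if bad.any():
        warnings.warn(
            f"{trait_id}: {int(bad.sum())} rows with p-value inconsistent "
            "with beta/se (|z| mismatch > 0.1)", stacklevel=2)
    if (np.abs(df["beta"]) >= 1).any():
        warnings.warn(f"{trait_id}: standardized |beta| >= 1 for some rows",
                      stacklevel=2)
    return df


def read_summary_stats(path, trait_id: str, trait_role: str,
                       dialect: Mapping | None = None,
                       sample_size_default: int | None = None,
                       sep: str = "\t") -> SummaryStatsTable:
    """Read a delimited summary-statistics table into canonical form.

    Accepts either ``(beta, se)`` or ``(z, n)`` effect columns; in the
    latter case effects are standardized as beta = z/sqrt(n), se = 1/sqrt(n).
    Rows failing validation are dropped with a logged count.
    """
    with _open_text(path) as fh:
        raw = pd.read_csv(fh, sep=sep)
    return _table_from_raw(raw, trait_id, trait_role, dialect,
                           sample_size_default)


def _table_from_raw(raw: pd.DataFrame, trait_id: str, trait_role: str,
                    dialect: Mapping | None,
                    sample_size_default: int | None) -> SummaryStatsTable:
    cols = _resolve_columns(raw.columns, dialect)
    for mandatory in ("variant_id", "ea", "oa", "pos"):
        if mandatory not in cols:
            raise ValueError(f"missing mandatory column: {mandatory}")
    has_beta = "beta" in cols and "se" in cols
    has_z = "z" in cols and ("n" in cols or sample_size_default is not None)
    if not has_beta and not has_z:
        raise ValueError("missing mandatory column: beta/se (or z with n)")

    df = pd.DataFrame({"variant_id": raw[cols["variant_id"]].astype(str)})
    df["chrom"] = pd.to_numeric(
        raw[cols["chrom"]].astype(str).str.replace("chr", "", regex=False),
        errors="coerce") if "chrom" in cols else np.nan
    df["pos"] = pd.to_numeric(raw[cols["pos"]], errors="coerce")
    df["ea"] = raw[cols["ea"]].astype(str).str.upper()
    df["oa"] = raw[cols["oa"]].astype(str).str.upper()
    df["eaf"] = pd.to_numeric(raw[cols["eaf"]], errors="coerce") if "eaf" in cols else np.nan
    if "n" in cols:
        df["n"] = pd.to_numeric(raw[cols["n"]], errors="coerce")
    else:
        if sample_size_default is None:
            raise ValueError("missing mandatory column: n (and no default given)")
        df["n"] = sample_size_default
    df["n"] = df["n"].fillna(sample_size_default if sample_size_default else np.nan)
    if df["n"].isna().any():
        raise ValueError("sample size missing for some rows with no default")

    if has_beta:
        df["beta"] = pd.to_numeric(raw[cols["beta"]], errors="coerce")
        df["se"] = pd.to_numeric(raw[cols["se"]], errors="coerce")
    else:
        z = pd.to_numeric(raw[cols["z"]], errors="coerce")
        df["beta"] = z / np.sqrt(df["n"])
        df["se"] = 1.0 / np.sqrt(df["n"])
    if "pvalue" in cols:
        df["pvalue"] = pd.to_numeric(raw[cols["pvalue"]], errors="coerce")
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            df["pvalue"] = 2 * stats.norm.sf(np.abs(df["beta"] / df["se"]))

    df = _validate_rows(df[CANONICAL_COLUMNS], trait_id)
    if df.empty:
        raise ValueError(f"{trait_id}: no valid rows after validation")
    return SummaryStatsTable(trait_id, trait_role, df, sample_size_default)


def read_multi_trait_stats(path, trait_role: str,
                           dialect: Mapping | None = None,
                           sample_size_default: int | None = None,
                           sep: str = "\t") -> dict[str, SummaryStatsTable]:
    """Split a long-format table (``phenotype_id`` column) into per-trait tables."""
    with _open_text(path) as fh:
        raw = pd.read_csv(fh, sep=sep)
    cols = _resolve_columns(raw.columns, dialect)
    if "phenotype_id" not in cols:
        raise ValueError("missing mandatory column: phenotype_id")
    out = {}
    for pid, grp in raw.groupby(cols["phenotype_id"]):
        out[str(pid)] = _table_from_raw(
            grp.drop(columns=[cols["phenotype_id"]]).reset_index(drop=True),
            str(pid), trait_role, dialect, sample_size_default)
    return out


def standardize(table: SummaryStatsTable) -> SummaryStatsTable:
    """Place effects on the per-SD scale: beta' = z/sqrt(n), se' = 1/sqrt(n).

    Idempotent: z = beta/se is unchanged by the transform. P-values are
    left untouched.
    """
    df = table.df.copy()
    if df["n"].isna().any():
        raise ValueError("sample size required for standardization")
    z = df["beta"] / df["se"]
    rootn = np.sqrt(df["n"].to_numpy(dtype=float))
    df["beta"] = z / rootn
    df["se"] = 1.0 / rootn
    return replace(table, df=df)


def read_ld_panel(matrix_path, index_path, sep: str = "\t") -> LDPanel:
    """Read a whitespace/tab-delimited square LD matrix with its sidecar
    variant index (variant_id, chrom, pos[, a1, a2])."""
    R = np.loadtxt(matrix_path)
    if R.ndim == 0:
        R = R.reshape(1, 1)
    elif R.ndim == 1:
        R = R.reshape(1, -1)
    index = pd.read_csv(index_path, sep=sep)
    index["variant_id"] = index["variant_id"].astype(str)
    return LDPanel(index, R)


def write_ld_panel(panel: LDPanel, matrix_path, index_path) -> None:
    np.savetxt(matrix_path, panel.R, fmt="%.8g")
    panel.index.to_csv(index_path, sep="\t", index=False)


def _is_palindromic(ea: pd.Series, oa: pd.Series) -> pd.Series:
    return pd.Series(
        [(a, b) in _PALINDROMIC for a, b in zip(ea, oa)], index=ea.index)


def harmonize(tables: Sequence[SummaryStatsTable], ld: LDPanel,
              af_tol: float = 0.05,
              reference_af: Mapping[str, float] | None = None,
              ) -> tuple[list[SummaryStatsTable], LDPanel]:
    """Align tables and the LD panel to a shared, oriented variant set.

    Keeps autosomal variants present in every table and the panel; aligns
    alleles to the first table's effect allele (flipping beta signs and AFs
    on swaps); removes palindromic (A/T, C/G) variants; removes variants
    whose oriented allele frequencies differ by more than ``af_tol``
    between any pair of tables. Output row order follows the LD panel.
    """
    if len(tables) < 2:
        raise ValueError("harmonization needs at least two tables")
    ref = tables[0].df
    autosomal = ref["chrom"].between(1, 22)
    shared = set(ref.loc[autosomal, "variant_id"])
    for t in tables[1:]:
        shared &= set(t.df.loc[t.df["chrom"].between(1, 22), "variant_id"])
    shared &= set(ld.variant_ids)
    order = [v for v in ld.variant_ids if v in shared]
    if not order:
        raise ValueError("no shared variants between tables and LD panel")

    ref_idx = ref.set_index("variant_id")
    aligned: list[pd.DataFrame] = []
    keep = set(order)
    for t in tables:
        df = t.df.set_index("variant_id").loc[order].reset_index()
        ref_ea = ref_idx.loc[order, "ea"].to_numpy()
        ref_oa = ref_idx.loc[order, "oa"].to_numpy()
        match = (df["ea"].to_numpy() == ref_ea) & (df["oa"].to_numpy() == ref_oa)
        swap = (df["ea"].to_numpy() == ref_oa) & (df["oa"].to_numpy() == ref_ea)
        bad = ~(match | swap)
        if bad.any():
            log.warning("%s: dropping %d variants with allele-set mismatch",
                        t.trait_id, int(bad.sum()))
            keep -= set(df.loc[bad, "variant_id"])
        df.loc[swap, "beta"] = -df.loc[swap, "beta"]
        df.loc[swap, "eaf"] = 1.0 - df.loc[swap, "eaf"]
        df.loc[swap, ["ea", "oa"]] = df.loc[swap, ["oa", "ea"]].to_numpy()
        aligned.append(df)

    pal = _is_palindromic(aligned[0]["ea"], aligned[0]["oa"])
    keep -= set(aligned[0].loc[pal.to_numpy(), "variant_id"])

    # AF agreement after orientation to the common effect allele
    afs = []
    for df in aligned:
        af = df["eaf"].copy()
        if af.isna().all() and reference_af is not None:
            af = df["variant_id"].map(reference_af)
        afs.append(af.to_numpy(dtype=float))
    afs = np.vstack(afs)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        spread = np.nanmax(afs, axis=0) - np.nanmin(afs, axis=0)
    af_bad = spread > af_tol
    keep -= set(np.asarray(aligned[0]["variant_id"])[af_bad])

    final = [v for v in order if v in keep]
    if not final:
        raise ValueError("no variants survived harmonization")
    out_tables = []
    for t, df in zip(tables, aligned):
        sub = df.set_index("variant_id").loc[final].reset_index()
        out_tables.append(replace(t, df=sub[CANONICAL_COLUMNS]))
    return out_tables, ld.subset(final)
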