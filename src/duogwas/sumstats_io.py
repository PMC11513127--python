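"""Reading, QC and allele harmonization of GWAS summary-statistic tables.

Input is tab-delimited text (optionally gzipped) with a header row; the
column mapping is configurable with conventional defaults
(SNP/CHR/POS/EA/NEA/EAF/BETA/SE/P/N).  Some published scans omit standard
errors, so an SE can be reconstructed from the coefficient and two-sided
p-value as ``|beta| / Phi^-1(1 - p/2)``; rows with p = 1 or beta = 0 carry
no information for that reconstruction and are dropped (counted).

Harmonization intersects two scans on variant ID, checks chrom/pos
consistency, orients both to a common effect allele (flipping the sign and
complementing the frequency where effect/other alleles are swapped), and
drops irreconcilable allele sets.  Strand-ambiguous (A/T, C/G) variants are
retained by default and matched by allele labels only — appropriate when
both scans come from the same strand-consistent study — or dropped via
``ambiguous="drop"``.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import special, stats

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_COLUMN_MAP",
    "SumstatsTable",
    "HarmonizeReport",
    "read_sumstats",
    "write_sumstats",
    "derive_se",
    "filter_underivable",
    "ensure_se",
    "harmonize_pair",
    "write_pairs",
]

#: canonical internal name -> default header label
DEFAULT_COLUMN_MAP = {
    "variant_id": "SNP",
    "chrom": "CHR",
    "pos": "POS",
    "effect_allele": "EA",
    "other_allele": "NEA",
    "eaf": "EAF",
    "beta": "BETA",
    "se": "SE",
    "p": "P",
    "n": "N",
}

_MANDATORY = ("variant_id", "chrom", "pos", "effect_allele", "other_allele", "beta", "p")
_AMBIGUOUS_PAIRS = {frozenset({"A", "T"}), frozenset({"C", "G"})}

SCAN_ROLES = ("fetal", "maternal", "paternal")


@dataclass
class SumstatsTable:
    """One harmonized scan: a DataFrame with canonical columns plus its role.

    Columns: variant_id, chrom, pos, effect_allele, other_allele, and the
    numeric eaf/beta/se/p/n where available.
    """

    df: pd.DataFrame
    scan_role: str
    n_default: Optional[int] = None

    def __post_init__(self):
        if self.scan_role not in SCAN_ROLES:
            raise ValueError(f"scan_role must be one of {SCAN_ROLES}")

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class HarmonizeReport:
    """Bookkeeping from a pairwise merge."""

    n_intersection: int = 0
    n_flipped: int = 0
    n_ambiguous: int = 0
    n_allele_mismatch: int = 0
    n_position_mismatch: int = 0
    notes: list = field(default_factory=list)


def _normalize_chrom(series: pd.Series) -> pd.Series:
    s = series.astype(str).str.strip().str.replace("^chr", "", case=False, regex=True)
    return s.str.upper().replace({"23": "X"})


def read_sumstats(
    path,
    scan_role: str,
    column_map: Optional[dict] = None,
    n_default: Optional[int] = None,
    duplicates: str = "error",
) -> SumstatsTable:
    """Read a tab-delimited (optionally .gz) summary-statistics file.

    ``column_map`` maps canonical names (see :data:`DEFAULT_COLUMN_MAP` keys)
    to the file's header labels; unspecified entries use the defaults.
    Rows whose beta or p fail to parse are dropped with a logged count.
    ``duplicates``: 'error' (default) or 'keep-first' for repeated variant
    IDs.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    raw = pd.read_csv(path, sep="\t", dtype=str, compression="infer")
    missing = [cmap[k] for k in _MANDATORY if cmap[k] not in raw.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory column(s) {missing}")

    present = {k: v for k, v in cmap.items() if v in raw.columns}
    df = raw[[v for v in present.values()]].copy()
    df.columns = list(present.keys())

    for col in ("eaf", "beta", "se", "p", "n", "pos"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")

    n0 = len(df)
    parse_ok = df["beta"].notna() & df["p"].notna() & df["pos"].notna()
    dropped = int(n0 - parse_ok.sum())
    if dropped:
        logger.info("%s: dropped %d row(s) with unparseable numerics", path, dropped)
    df = df[parse_ok].copy()
    if df.empty:
        raise ValueError(f"{path}: no parseable rows")

    df["pos"] = df["pos"].astype(np.int64)
    df["chrom"] = _normalize_chrom(df["chrom"])
    df["effect_allele"] = df["effect_allele"].str.upper()
    df["other_allele"] = df["other_allele"].str.upper()

    dup = df["variant_id"].duplicated(keep="first")
    if dup.any():
        if duplicates == "keep-first":
            logger.info("%s: kept first of %d duplicated variant ID(s)", path, int(dup.sum()))
            df = df[~dup].copy()
        else:
            ids = df.loc[dup, "variant_id"].unique()[:5]
            raise ValueError(f"{path}: duplicated variant IDs (e.g. {list(ids)}); "
                             "pass duplicates='keep-first' to keep the first occurrence")

    df = df.reset_index(drop=True)
    return SumstatsTable(df=df, scan_role=scan_role, n_default=n_default)


def write_sumstats(table: SumstatsTable, path, column_map: Optional[dict] = None) -> None:
    """Write a scan back to tab-delimited text (gzip if path ends .gz)."""
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    out = table.df.rename(columns={k: v for k, v in cmap.items() if k in table.df.columns})
    out.to_csv(path, sep="\t", index=False)


def derive_se(beta, p, log_p=None):
    """Standard error from a coefficient and its two-sided p-value.

    ``se = |beta| / z`` with ``z`` the upper-tail normal quantile at p/2.
    Pass ``log_p`` (natural log of p) for p-values below the smallest
    positive double; the quantile is then taken on the log scale so the
    result neither overflows nor collapses to zero.  Scalars or arrays.

    Raises ValueError for p = 1 or beta = 0 (scalar inputs), where no SE is
    derivable; array inputs yield NaN at such entries.
    """
    beta = np.asarray(beta, dtype=float)
    scalar = beta.ndim == 0
    if log_p is not None:
        lp = np.asarray(log_p, dtype=float)
        z = -special.ndtri_exp(lp - np.log(2.0))  # upper-tail quantile at p/2
        bad = (lp >= 0) | (beta == 0)
    else:
        p = np.asarray(p, dtype=float)
        if np.any((p <= 0) | (p > 1)):
            raise ValueError("p-values must lie in (0, 1]")
        with np.errstate(divide="ignore"):
            z = stats.norm.isf(p / 2.0)
        bad = (p >= 1) | (beta == 0)
    if scalar and bad:
        raise ValueError("SE underivable: p = 1 or beta = 0")
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.abs(beta) / z
    se = np.where(bad, np.nan, se)
    return float(se) if scalar else se


def filter_underivable(table: SumstatsTable):
    """Drop rows with p = 1 or beta = 0, where an SE cannot be derived.

    Returns ``(filtered_table, drop_count)``.
    """
    df = table.df
    bad = (df["p"] >= 1.0) | (df["beta"] == 0.0)
    drop_count = int(bad.sum())
    if drop_count:
        logger.info("%s scan: removed %d row(s) with p = 1 or beta = 0",
                    table.scan_role, drop_count)
    out = SumstatsTable(df=df[~bad].reset_index(drop=True), scan_role=table.scan_role,
                        n_default=table.n_default)
    return out, drop_count


def ensure_se(table: SumstatsTable) -> SumstatsTable:
    """Fill missing SEs from beta and p (rows must already pass
    :func:`filter_underivable`)."""
    df = table.df.copy()
    if "se" not in df.columns:
        df["se"] = np.nan
    need = df["se"].isna()
    if need.any():
        df.loc[need, "se"] = derive_se(df.loc[need, "beta"].to_numpy(),
                                       df.loc[need, "p"].to_numpy())
    return SumstatsTable(df=df, scan_role=table.scan_role, n_default=table.n_default)


def _is_ambiguous(ea: pd.Series, oa: pd.Series) -> pd.Series:
    return ((ea == "A") & (oa == "T")) | ((ea == "T") & (oa == "A")) | \
           ((ea == "C") & (oa == "G")) | ((ea == "G") & (oa == "C"))


def harmonize_pair(scan1: SumstatsTable, scan2: SumstatsTable,
                   ambiguous: str = "keep"):
    """Merge two scans on variant ID and orient to a common effect allele.

    Returns ``(pairs, report)`` where ``pairs`` is a DataFrame with columns
    variant_id, chrom, pos, effect_allele, other_allele, b_f, se_f, b_m,
    se_m (roles taken from the scans; the first scan's orientation wins),
    plus eaf from the first scan where available.

    Where scan2's effect/other alleles are swapped relative to scan1, its
    beta is negated (and eaf complemented); variants whose allele sets do
    not match at all are dropped and counted.  ``ambiguous="drop"`` removes
    strand-ambiguous variants instead of the default label-matching.
    """
    report = HarmonizeReport()
    suffixes = ("_1", "_2")
    m = scan1.df.merge(scan2.df, on="variant_id", how="inner", suffixes=suffixes)
    if m.empty:
        raise ValueError("empty intersection between scans")
    report.n_intersection = len(m)

    pos_ok = (m["chrom_1"] == m["chrom_2"]) & (m["pos_1"] == m["pos_2"])
    report.n_position_mismatch = int((~pos_ok).sum())
    m = m[pos_ok]

    amb = _is_ambiguous(m["effect_allele_1"], m["other_allele_1"])
    report.n_ambiguous = int(amb.sum())
    if ambiguous == "drop":
        m = m[~amb]
    elif ambiguous != "keep":
        raise ValueError("ambiguous must be 'keep' or 'drop'")

    same = (m["effect_allele_1"] == m["effect_allele_2"]) & \
           (m["other_allele_1"] == m["other_allele_2"])
    swapped = (m["effect_allele_1"] == m["other_allele_2"]) & \
              (m["other_allele_1"] == m["effect_allele_2"])
    report.n_allele_mismatch = int((~(same | swapped)).sum())
    m = m[same | swapped].copy()
    if m.empty:
        raise ValueError("no variants with reconcilable alleles")

    flip = (m["effect_allele_1"] == m["other_allele_2"]) & \
           (m["other_allele_1"] == m["effect_allele_2"]) & \
           ~((m["effect_allele_1"] == m["effect_allele_2"]) &
             (m["other_allele_1"] == m["other_allele_2"]))
    report.n_flipped = int(flip.sum())
    m.loc[flip, "beta_2"] = -m.loc[flip, "beta_2"]
    if "eaf_2" in m.columns:
        m.loc[flip, "eaf_2"] = 1.0 - m.loc[flip, "eaf_2"]

    role_suffix = {scan1.scan_role: "_1", scan2.scan_role: "_2"}
    if len(role_suffix) != 2:
        raise ValueError("the two scans must have different roles")

    def col(role_letter, which):
        # role letters: f(etal), m(aternal), p(aternal)
        role = {"f": "fetal", "m": "maternal", "p": "paternal"}[role_letter]
        return m[f"{which}{role_suffix[role]}"].to_numpy()

    out = pd.DataFrame({
        "variant_id": m["variant_id"].to_numpy(),
        "chrom": m["chrom_1"].to_numpy(),
        "pos": m["pos_1"].to_numpy(),
        "effect_allele": m["effect_allele_1"].to_numpy(),
        "other_allele": m["other_allele_1"].to_numpy(),
    })
    for letter in ("f", "m", "p"):
        role = {"f": "fetal", "m": "maternal", "p": "paternal"}[letter]
        if role in role_suffix:
            out[f"b_{letter}"] = col(letter, "beta")
            out[f"se_{letter}"] = col(letter, "se")
    if "eaf_1" in m.columns:
        out["eaf"] = m["eaf_1"].to_numpy()

    se_cols = [c for c in out.columns if c.startswith("se_")]
    bad_se = ~np.all([out[c].to_numpy() > 0 for c in se_cols], axis=0)
    if bad_se.any():
        report.notes.append(f"dropped {int(bad_se.sum())} variant(s) with non-positive SE")
        out = out[~bad_se]

    out = out.sort_values(["chrom", "pos", "variant_id"]).reset_index(drop=True)
    return out, report


def write_pairs(pairs: pd.DataFrame, path) -> None:
    """Write the harmonized per-variant pair table as tab-delimited text."""
    pairs.to_csv(path, sep="\t", index=False)
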