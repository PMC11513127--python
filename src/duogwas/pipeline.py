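"""Genome-wide orchestration: harmonize, test, classify, clump.

Chains the modules over a harmonized pair table: per-variant conditional
estimates, the 2-df joint test, and both one-df meta-analyses; then
classifies genome-wide significant variants by their conditional p-values
and reduces them to loci by distance-based greedy clumping (no LD reference
panel is required; an r^2-aware clump can be layered on top where LD is
available).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import joint_test, sumstats_io
from .conditional import ConditionalResult
from .coupling import CouplingEstimate, sampling_cov
from .meta import meta_fetal, meta_maternal

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "LocusCall",
    "analyze_pairs",
    "classify_locus",
    "classify_array",
    "greedy_clump",
    "run_genome_wide",
    "strategy_counts",
]

CLASSIFICATIONS = ("fetal_only", "maternal_only", "both_concordant", "both_discordant",
                   "undetermined")


@dataclass
class PipelineConfig:
    """Run-level settings; mirrors the YAML config and CLI flags."""

    intercept: float = 0.0
    alpha_1df: float = joint_test.ALPHA_1DF
    alpha_2df: float = joint_test.ALPHA_2DF
    alpha_conditional: float = 0.05
    clump_window_bp: int = 500_000
    ambiguous: str = "keep"
    duplicates: str = "error"
    column_map: Optional[dict] = None


@dataclass
class LocusCall:
    """One clumped locus, led by its smallest-p significant variant."""

    variant_id: str
    chrom: str
    pos: int
    log_p: float
    discovery_flags: list
    classification: str
    n_members: int = 1


def analyze_pairs(pairs: pd.DataFrame, coupling: CouplingEstimate,
                  config: Optional[PipelineConfig] = None) -> pd.DataFrame:
    """Attach conditional, 2-df and meta columns to a harmonized pair table.

    Input must have columns b_f, se_f, b_m, se_m (from
    :func:`duogwas.sumstats_io.harmonize_pair`).
    """
    cfg = config or PipelineConfig()
    b_f = pairs["b_f"].to_numpy(float)
    b_m = pairs["b_m"].to_numpy(float)
    se_bf = pairs["se_f"].to_numpy(float)
    se_bm = pairs["se_m"].to_numpy(float)
    var_bf, var_bm = se_bf**2, se_bm**2
    cov_b = sampling_cov(coupling, se_bf, se_bm)

    cond = ConditionalResult.from_unconditional(b_f, b_m, var_bf, var_bm, cov_b)
    stat, p2, logp2, ok = joint_test.t2df_arrays(
        cond.beta_f_hat, cond.beta_m_hat, cond.se_f**2, cond.se_m**2, cond.cov_fm
    )
    fm = meta_fetal(b_f, var_bf, b_m, var_bm, cov_b)
    mm = meta_maternal(b_f, var_bf, b_m, var_bm, cov_b)

    out = pairs.copy()
    # unconditional per-scan tests (the traditional separate-GWAS strategy)
    from .conditional import two_sided_logp, two_sided_p

    z_uf, z_um = b_f / se_bf, b_m / se_bm
    out["p_scan_f"] = two_sided_p(z_uf)
    out["logp_scan_f"] = two_sided_logp(z_uf)
    out["p_scan_m"] = two_sided_p(z_um)
    out["logp_scan_m"] = two_sided_logp(z_um)
    out["beta_f"] = cond.beta_f_hat
    out["se_beta_f"] = cond.se_f
    out["p_f"] = cond.p_f
    out["logp_f"] = cond.logp_f
    out["beta_m"] = cond.beta_m_hat
    out["se_beta_m"] = cond.se_m
    out["p_m"] = cond.p_m
    out["logp_m"] = cond.logp_m
    out["cov_fm"] = cond.cov_fm
    out["t2df_stat"] = stat
    out["t2df_df"] = 2
    out["t2df_p"] = p2
    out["t2df_logp"] = logp2
    out["t2df_ok"] = ok
    out["beta_fmeta"] = fm.beta_meta
    out["se_fmeta"] = fm.se_meta
    out["p_fmeta"] = fm.p
    out["logp_fmeta"] = fm.log_p
    out["beta_mmeta"] = mm.beta_meta
    out["se_mmeta"] = mm.se_meta
    out["p_mmeta"] = mm.p
    out["logp_mmeta"] = mm.log_p
    out["meta_min_p"] = np.minimum(fm.p, mm.p)

    n_flag = int((~ok).sum())
    if n_flag:
        logger.warning("%d variant(s) flagged: conditional Sigma not positive definite", n_flag)
    return out


def classify_locus(p_f: float, p_m: float, beta_f: float, beta_m: float,
                   alpha: float = 0.05) -> str:
    """Mode-of-action call from conditional p-values and effect signs.

    fetal_only / maternal_only when exactly one conditional test is below
    ``alpha``; both_concordant / both_discordant (by sign of the product of
    the conditional effects) when both are; undetermined otherwise.
    """
    f_sig, m_sig = p_f < alpha, p_m < alpha
    if f_sig and m_sig:
        return "both_concordant" if beta_f * beta_m > 0 else "both_discordant"
    if f_sig:
        return "fetal_only"
    if m_sig:
        return "maternal_only"
    return "undetermined"


def classify_array(df: pd.DataFrame, alpha: float = 0.05) -> np.ndarray:
    """Vectorised :func:`classify_locus` over an analyzed table."""
    f_sig = df["p_f"].to_numpy() < alpha
    m_sig = df["p_m"].to_numpy() < alpha
    prod = df["beta_f"].to_numpy() * df["beta_m"].to_numpy()
    out = np.full(len(df), "undetermined", dtype=object)
    out[f_sig & ~m_sig] = "fetal_only"
    out[m_sig & ~f_sig] = "maternal_only"
    out[f_sig & m_sig & (prod > 0)] = "both_concordant"
    out[f_sig & m_sig & (prod <= 0)] = "both_discordant"
    return out


def _discovery_flags(row: pd.Series, alpha_1df: float, alpha_2df: float) -> list:
    """Which strategies called this variant significant (strict <)."""
    la1, la2 = np.log(alpha_1df), np.log(alpha_2df)
    flags = []
    if row["logp_scan_f"] < la1:
        flags.append("separate_fetal")
    if row["logp_scan_m"] < la1:
        flags.append("separate_maternal")
    if row["logp_fmeta"] < la1:
        flags.append("meta_fetal")
    if row["logp_mmeta"] < la1:
        flags.append("meta_maternal")
    if row["t2df_ok"] and row["t2df_logp"] < la2:
        flags.append("t2df")
    return flags


def greedy_clump(results: pd.DataFrame, alpha: float, window_bp: int = 500_000,
                 logp_col: str = "t2df_logp",
                 alpha_1df: Optional[float] = None,
                 alpha_2df: Optional[float] = None,
                 alpha_conditional: float = 0.05) -> list:
    """Distance-based greedy clumping of significant variants into loci.

    Repeatedly takes the smallest-p significant variant (ties broken by
    chrom, pos), suppresses significant variants within ``window_bp`` on the
    same chromosome, and emits a :class:`LocusCall`.  Significance is
    ``log p < log alpha`` on ``logp_col`` (log scale avoids underflow ties
    at p = 0).
    """
    a1 = alpha if alpha_1df is None else alpha_1df
    a2 = alpha if alpha_2df is None else alpha_2df
    sig = results[results[logp_col] < np.log(alpha)].copy()
    if logp_col == "t2df_logp" and "t2df_ok" in sig.columns:
        sig = sig[sig["t2df_ok"]]
    sig = sig.sort_values([logp_col, "chrom", "pos"], kind="mergesort").reset_index(drop=True)
    alive = np.ones(len(sig), dtype=bool)
    chrom = sig["chrom"].to_numpy()
    pos = sig["pos"].to_numpy(np.int64)
    loci: list[LocusCall] = []
    for i in range(len(sig)):
        if not alive[i]:
            continue
        members = alive & (chrom == chrom[i]) & (np.abs(pos - pos[i]) <= window_bp)
        n_members = int(members.sum())
        alive &= ~members
        row = sig.iloc[i]
        loci.append(LocusCall(
            variant_id=str(row["variant_id"]),
            chrom=str(row["chrom"]),
            pos=int(row["pos"]),
            log_p=float(row[logp_col]),
            discovery_flags=_discovery_flags(row, a1, a2),
            classification=classify_locus(row["p_f"], row["p_m"], row["beta_f"],
                                          row["beta_m"], alpha=alpha_conditional),
            n_members=n_members,
        ))
    loci.sort(key=lambda lc: (lc.chrom, lc.pos))
    return loci


def strategy_counts(results: pd.DataFrame, alpha_1df: float, alpha_2df: float) -> dict:
    """Per-strategy significant-variant counts plus overlap bookkeeping.

    The inclusion-exclusion identity ``|meta| + |t2df| - |both| = |either|``
    is part of the returned dict so consumers can check consistency.
    """
    la1, la2 = np.log(alpha_1df), np.log(alpha_2df)
    meta_sig = (results["logp_fmeta"].to_numpy() < la1) | (results["logp_mmeta"].to_numpy() < la1)
    t2_sig = results["t2df_ok"].to_numpy() & (results["t2df_logp"].to_numpy() < la2)
    sep_sig = (results["logp_scan_f"].to_numpy() < la1) | (results["logp_scan_m"].to_numpy() < la1)
    return {
        "separate": int(sep_sig.sum()),
        "meta": int(meta_sig.sum()),
        "t2df": int(t2_sig.sum()),
        "meta_and_t2df": int((meta_sig & t2_sig).sum()),
        "meta_only": int((meta_sig & ~t2_sig).sum()),
        "t2df_only": int((t2_sig & ~meta_sig).sum()),
        "meta_or_t2df": int((meta_sig | t2_sig).sum()),
    }


def run_genome_wide(fetal_path, maternal_path, config: Optional[PipelineConfig] = None,
                    chunk_rows: int = 500_000):
    """Full run from two summary-statistic files.

    Reads, QC-filters and SE-fills both scans, harmonizes, analyzes in
    row-chunks (bounded memory), clumps with the 2-df statistic and with the
    meta minimum-p, and returns ``(variants, loci_t2df, loci_meta, log)``.
    Output ordering is deterministic (chrom, pos).
    """
    cfg = config or PipelineConfig()
    log: dict = {}
    tables = {}
    for role, path in (("fetal", fetal_path), ("maternal", maternal_path)):
        t = sumstats_io.read_sumstats(path, scan_role=role, column_map=cfg.column_map,
                                      duplicates=cfg.duplicates)
        t, dropped = sumstats_io.filter_underivable(t)
        t = sumstats_io.ensure_se(t)
        log[f"{role}_rows"] = len(t)
        log[f"{role}_underivable_dropped"] = dropped
        tables[role] = t

    pairs, report = sumstats_io.harmonize_pair(tables["fetal"], tables["maternal"],
                                               ambiguous=cfg.ambiguous)
    log["harmonize"] = report
    log["n_pairs"] = len(pairs)

    coupling = CouplingEstimate.from_intercept(cfg.intercept)
    chunks = [analyze_pairs(pairs.iloc[i:i + chunk_rows], coupling, cfg)
              for i in range(0, len(pairs), chunk_rows)]
    variants = pd.concat(chunks, ignore_index=True)
    variants = variants.sort_values(["chrom", "pos", "variant_id"],
                                    kind="mergesort").reset_index(drop=True)
    log["n_flagged"] = int((~variants["t2df_ok"]).sum())
    log["strategy_counts"] = strategy_counts(variants, cfg.alpha_1df, cfg.alpha_2df)

    loci_t2df = greedy_clump(variants, alpha=cfg.alpha_2df, window_bp=cfg.clump_window_bp,
                             logp_col="t2df_logp", alpha_1df=cfg.alpha_1df,
                             alpha_2df=cfg.alpha_2df, alpha_conditional=cfg.alpha_conditional)
    meta_view = variants.assign(meta_min_logp=np.minimum(variants["logp_fmeta"],
                                                         variants["logp_mmeta"]))
    loci_meta = greedy_clump(meta_view, alpha=cfg.alpha_1df, window_bp=cfg.clump_window_bp,
                             logp_col="meta_min_logp", alpha_1df=cfg.alpha_1df,
                             alpha_2df=cfg.alpha_2df, alpha_conditional=cfg.alpha_conditional)
    return variants, loci_t2df, loci_meta, log


def loci_to_frame(loci: list) -> pd.DataFrame:
    """Tabulate LocusCalls for TSV export."""
    return pd.DataFrame([{
        "variant_id": lc.variant_id,
        "chrom": lc.chrom,
        "pos": lc.pos,
        "log_p": lc.log_p,
        "discovery_flags": ",".join(lc.discovery_flags),
        "classification": lc.classification,
        "n_members": lc.n_members,
    } for lc in loci])
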