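"""Tumor mutation burden from annotated somatic variant tables.

Input is a MAF-like table of pre-annotated variants (annotation itself —
caller, ClinVar, Cancer Gene Census — is upstream and out of scope; the
flags are taken as given).  ``filter_somatic`` applies the quality / VAF /
common-SNP gate; ``compute_tmb`` counts single-nucleotide variants over the
callable genome size (default ~50 Mb) and classifies the burden:
ultra-hypermutant (TMB > 100 SNV/Mb), hypermutant (10 <= TMB <= 100),
non-hypermutant (TMB < 10).  Indels are excluded from the TMB numerator and
reported separately.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

VARIANT_COLUMNS = ("chrom", "pos", "ref", "alt", "vaf", "consequence",
                   "quality_pass", "common_snp", "clinvar_class", "cgc_listed")

IMPACTFUL_CONSEQUENCES = frozenset({"missense", "nonsense", "frameshift_indel", "splice_region"})
BENIGN_CLINVAR = frozenset({"benign", "likely_benign"})

DEFAULT_CALLABLE_MB = 50.0


@dataclass(frozen=True)
class TMBResult:
    n_snv: int
    n_indel: int
    callable_mb: float
    tmb: float
    tmb_class: str  # ultra | hyper | non


def _check_columns(variants: pd.DataFrame, needed: tuple[str, ...]) -> None:
    missing = [c for c in needed if c not in variants.columns]
    if missing:
        raise ValueError(f"variant table missing columns: {missing}")


def validate_variants(variants: pd.DataFrame) -> pd.DataFrame:
    _check_columns(variants, VARIANT_COLUMNS)
    if ((variants["vaf"] < 0) | (variants["vaf"] > 1)).any():
        raise ValueError("VAF outside [0, 1]")
    if (variants["pos"] < 1).any():
        raise ValueError("positions must be 1-based (>= 1)")
    return variants


def filter_somatic(variants: pd.DataFrame, min_vaf: float = 0.05) -> pd.DataFrame:
    """Keep quality-passing variants with VAF >= min_vaf (inclusive) that are
    not common SNPs."""
    _check_columns(variants, ("vaf", "quality_pass", "common_snp"))
    keep = (variants["quality_pass"].astype(bool)
            & (variants["vaf"] >= min_vaf)
            & ~variants["common_snp"].astype(bool))
    return variants.loc[keep].copy()


def filter_impactful(variants: pd.DataFrame) -> pd.DataFrame:
    """Keep coding/splice variants that are not ClinVar (likely-)benign and
    are listed in the Cancer Gene Census."""
    _check_columns(variants, ("consequence", "clinvar_class", "cgc_listed"))
    keep = (variants["consequence"].isin(IMPACTFUL_CONSEQUENCES)
            & ~variants["clinvar_class"].isin(BENIGN_CLINVAR)
            & variants["cgc_listed"].astype(bool))
    return variants.loc[keep].copy()


def is_snv(variants: pd.DataFrame) -> pd.Series:
    """Single-base ref and alt, both plain nucleotides."""
    _check_columns(variants, ("ref", "alt"))
    nt = {"A", "C", "G", "T"}
    ref = variants["ref"].astype(str)
    alt = variants["alt"].astype(str)
    return (ref.str.len() == 1) & (alt.str.len() == 1) & ref.isin(nt) & alt.isin(nt)


def classify_tmb(tmb: float) -> str:
    """ultra: TMB > 100; hyper: 10 <= TMB <= 100; non: TMB < 10."""
    if tmb > 100:
        return "ultra"
    if tmb >= 10:
        return "hyper"
    return "non"


def compute_tmb(variants: pd.DataFrame, callable_mb: float = DEFAULT_CALLABLE_MB) -> TMBResult:
    """SNVs per callable megabase from an already somatic-filtered table."""
    if callable_mb <= 0:
        raise ValueError("callable_mb must be positive")
    snv_mask = is_snv(variants)
    n_snv = int(snv_mask.sum())
    n_indel = int((~snv_mask).sum())
    tmb = n_snv / callable_mb
    return TMBResult(n_snv=n_snv, n_indel=n_indel, callable_mb=callable_mb,
                     tmb=tmb, tmb_class=classify_tmb(tmb))


def tmb_per_sample(variants: pd.DataFrame, callable_mb: float = DEFAULT_CALLABLE_MB,
                   min_vaf: float = 0.05) -> pd.DataFrame:
    """Somatic-filter and compute TMB for each sample in a multi-sample table
    (requires a ``sample_id`` column)."""
    _check_columns(variants, ("sample_id",))
    rows = []
    for sample_id, sub in variants.groupby("sample_id", sort=False, observed=True):
        res = compute_tmb(filter_somatic(sub, min_vaf=min_vaf), callable_mb=callable_mb)
        rows.append({"sample_id": sample_id, "n_snv": res.n_snv, "n_indel": res.n_indel,
                     "tmb": res.tmb, "tmb_class": res.tmb_class})
    return pd.DataFrame(rows).set_index("sample_id")
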