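"""Signature and gene-set scoring on transformed expression.

Three scoring routes are provided:

* ``linear_score`` — weighted sums of log2 expression (the tumor
  inflammation signature and PROGENy-style coefficient matrices are both
  of this form): score_s = sum_g w_g * expr[g, s].

* ``gsva_score`` — a native implementation of gene-set variation analysis:
  per-gene Gaussian-kernel CDF estimation across samples, sample-wise rank
  normalization into a symmetric statistic |p/2 - rank|, a weighted
  Kolmogorov-Smirnov random walk down the gene ranking, and the max-positive
  plus max-negative deviation ("maxdiff") enrichment score.

* ``harmonize_rnaseq`` — brings RNA-seq TPM matrices onto a scale comparable
  with nCounter log2 counts: restrict to protein-coding genes, rescale to
  TPM (columns sum to 1e6), multiply by 10, log2 with a +1 pseudocount.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtr
from scipy.stats import rankdata

from .nanostring import CountsMatrix, GeneSetCollection, SignatureDefinition


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of transformed expression."""

    data: pd.DataFrame  # index = genes, columns = samples
    scale: str = "log2_counts"  # log2_counts | log2_tpm10 | zscore

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.data.to_numpy(float))):
            raise ValueError("expression matrix contains non-finite values")
        if self.data.index.duplicated().any():
            raise ValueError("duplicate gene names")

    @property
    def genes(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def samples(self) -> list[str]:
        return self.data.columns.tolist()


def log2_transform(counts: CountsMatrix, floor: float = 1.0) -> ExpressionMatrix:
    """log2(max(count, floor)) of a fully normalized counts matrix, genes x samples."""
    if counts.stage != "fully_normalized":
        raise ValueError(f"log2_transform expects fully normalized counts, got {counts.stage!r}")
    values = counts.data.to_numpy(float)
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite counts")
    data = pd.DataFrame(np.log2(np.maximum(values, floor)).T,
                        index=counts.probes, columns=counts.samples)
    return ExpressionMatrix(data=data, scale="log2_counts")


def zscore_rows(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Per-gene z-scoring across samples (for coefficient-matrix scores)."""
    values = expr.data.to_numpy(float)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    if np.any(sd == 0):
        bad = [expr.genes[i] for i in np.where(sd[:, 0] == 0)[0]]
        raise ValueError(f"zero-variance genes cannot be z-scored: {bad}")
    z = (values - values.mean(axis=1, keepdims=True)) / sd
    return ExpressionMatrix(data=pd.DataFrame(z, index=expr.data.index, columns=expr.data.columns),
                            scale="zscore")


def linear_score(expr: ExpressionMatrix, sig: SignatureDefinition) -> pd.Series:
    """Weighted sum of expression rows; errors on missing genes (no silent subsetting)."""
    missing = [g for g in sig.genes if g not in expr.data.index]
    if missing:
        raise KeyError(f"signature {sig.name!r} genes missing from expression matrix: {missing}")
    sub = expr.data.loc[sig.genes].to_numpy(float)
    scores = sig.entries.to_numpy(float) @ sub
    out = pd.Series(scores, index=expr.data.columns, name=sig.name)
    return out


def score_signatures(expr: ExpressionMatrix, sigs: Sequence[SignatureDefinition]) -> pd.DataFrame:
    """Score several signatures at once; rows = signatures, columns = samples."""
    return pd.DataFrame({s.name: linear_score(expr, s) for s in sigs}).T


def gsva_score(expr: ExpressionMatrix, sets: GeneSetCollection, tau: float = 1.0) -> pd.DataFrame:
    """Gene-set variation analysis scores, one row per set, one column per sample.

    Scores depend only on the expression values, not on the gene order of the
    input matrix.  Requires >= 3 samples (the kernel CDF is estimated across
    samples); a set with no genes in the matrix is an error.
    """
    X = expr.data.to_numpy(float)
    p, n = X.shape
    if n < 3:
        raise ValueError("gsva_score requires at least 3 samples")
    genes = expr.data.index

    # Per-gene Gaussian kernel CDF across samples, bandwidth s_i / 4.
    sd = X.std(axis=1, ddof=1, keepdims=True)
    h = sd / 4.0
    Z = np.empty_like(X)
    for i in range(p):
        if h[i, 0] == 0:
            Z[i, :] = 0.5
        else:
            Z[i, :] = ndtr((X[i, :, None] - X[i, None, :]) / h[i, 0]).mean(axis=1)

    # Sample-wise rank normalization: highest statistic gets rank p; the
    # symmetric statistic |p/2 - rank| up-weights both expression extremes.
    ranks = np.apply_along_axis(rankdata, 0, Z)  # 1..p per column
    weight = np.abs(p / 2.0 - ranks) ** tau
    order = np.argsort(-Z, axis=0, kind="stable")  # walk from highest to lowest

    scores = np.zeros((len(sets), n))
    set_names = list(sets)
    gene_pos = {g: i for i, g in enumerate(genes)}
    for k, name in enumerate(set_names):
        members = [gene_pos[g] for g in sets[name] if g in gene_pos]
        if not members:
            raise ValueError(f"gene set {name!r} has no genes in the expression matrix")
        in_set = np.zeros(p, dtype=bool)
        in_set[members] = True
        m = in_set.sum()
        if m == p:
            raise ValueError(f"gene set {name!r} covers every gene; the walk is degenerate")
        for j in range(n):
            ord_j = order[:, j]
            set_mask = in_set[ord_j]
            w = np.where(set_mask, weight[ord_j, j], 0.0)
            denom = w.sum()
            inc = np.cumsum(w) / denom
            dec = np.cumsum(~set_mask) / (p - m)
            nu = inc - dec
            scores[k, j] = max(nu.max(), 0.0) + min(nu.min(), 0.0)
    return pd.DataFrame(scores, index=set_names, columns=expr.data.columns)


def harmonize_rnaseq(tpm: pd.DataFrame, coding_genes: Sequence[str],
                     range_factor: float = 10.0) -> ExpressionMatrix:
    """Protein-coding TPM rescale + log2 for cross-platform comparison.

    ``tpm`` is genes x samples, nonnegative.  Values are subset to
    ``coding_genes``, rescaled so each sample sums to 1e6, multiplied by
    ``range_factor`` (10 brings TPMs into the nCounter count range) and
    log2(x + 1)-transformed so zeros map to zero.
    """
    if (tpm.to_numpy(float) < 0).any():
        raise ValueError("TPM matrix must be nonnegative")
    coding = [g for g in coding_genes if g in tpm.index]
    if not coding:
        raise ValueError("no coding genes found in the matrix")
    sub = tpm.loc[coding].to_numpy(float)
    col_sums = sub.sum(axis=0)
    zero_cols = np.where(col_sums == 0)[0]
    if len(zero_cols):
        bad = [tpm.columns[i] for i in zero_cols]
        raise ValueError(f"samples with all-zero coding genes: {bad}")
    rescaled = sub / col_sums * 1e6
    data = pd.DataFrame(np.log2(range_factor * rescaled + 1.0),
                        index=coding, columns=tpm.columns)
    return ExpressionMatrix(data=data, scale="log2_tpm10")
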