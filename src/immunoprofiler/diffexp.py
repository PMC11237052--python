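"""Per-gene two-group differential expression on log2 expression.

Row-wise t-tests (Welch unequal-variance by default; the pooled-variance
variant is available) with Benjamini-Hochberg correction.  log2FC is
mean(groupA) - mean(groupB) on the log2 scale.  Genes with zero variance in
both groups get t = 0, p = 1 rather than NaN.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .scoring import ExpressionMatrix


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    arr = np.asarray(pvals, dtype=float)
    if arr.size == 0:
        return arr.copy()
    if np.any(~np.isfinite(arr)) or np.any(arr <= 0) or np.any(arr > 1):
        raise ValueError("p-values must lie in (0, 1]")
    _, q, _, _ = multipletests(arr, method="fdr_bh")
    return q


def de_test(expr: ExpressionMatrix, group_a: Sequence[str], group_b: Sequence[str],
            welch: bool = True) -> pd.DataFrame:
    """Per-gene t-test of group A vs group B.

    Returns a DataFrame indexed by gene with columns log2FC, t, p, q,
    sorted by q then descending |log2FC|.
    """
    group_a, group_b = list(group_a), list(group_b)
    overlap = set(group_a) & set(group_b)
    if overlap:
        raise ValueError(f"groups overlap: {sorted(overlap)}")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least 2 samples")
    for name, grp in (("A", group_a), ("B", group_b)):
        missing = [s for s in grp if s not in expr.data.columns]
        if missing:
            raise KeyError(f"group {name} samples not in matrix: {missing}")

    A = expr.data[group_a].to_numpy(float)
    B = expr.data[group_b].to_numpy(float)
    log2fc = A.mean(axis=1) - B.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(A, B, axis=1, equal_var=not welch)
    degenerate = (A.var(axis=1, ddof=1) == 0) & (B.var(axis=1, ddof=1) == 0)
    t = np.where(degenerate, 0.0, t)
    p = np.where(degenerate, 1.0, p)
    # identical means with equal variances can produce p=0+eps issues; clamp
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    q = bh_adjust(p)
    out = pd.DataFrame({"log2FC": log2fc, "t": t, "p": p, "q": q}, index=expr.data.index)
    out.index.name = "gene"
    return out.sort_values(["q", "log2FC"], key=lambda s: s.abs() if s.name == "log2FC" else s,
                           ascending=[True, False])
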