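"""Subsampled consensus clustering of expression profiles.

The procedure (Monti-style, as popularized by ConsensusClusterPlus): for
each candidate cluster number k, repeatedly subsample the samples, run
average-linkage hierarchical clustering on the Pearson-correlation distance
(d = 1 - r), and record how often each pair of samples lands in the same
cluster among the resamples where both were drawn.  The resulting consensus
matrix (co-cluster count / co-sampled count) is itself clustered to give the
final assignment, and its empirical CDF / delta-area curve drives the choice
of k.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .scoring import ExpressionMatrix


@dataclass
class ConsensusResult:
    samples: list[str]
    k_range: list[int]
    consensus: dict[int, np.ndarray]        # k -> samples x samples in [0,1]
    assignments: dict[int, pd.Series]       # k -> sample -> cluster id (1-based)
    cdf: dict[int, tuple[np.ndarray, np.ndarray]]  # k -> (grid, empirical CDF)
    area: dict[int, float]                  # area under consensus CDF
    delta_area: dict[int, float]            # relative delta area (k=2: the raw area)
    chosen_k: int
    low_confidence: bool
    consensus_gap: dict[int, float]         # within-minus-between mean consensus
    rng_seed: int
    linkage_method: str = "average"


def pearson_distance(expr: ExpressionMatrix) -> pd.DataFrame:
    """Sample-sample distance d(i,j) = 1 - Pearson r of expression profiles."""
    X = expr.data.to_numpy(float)  # genes x samples
    if X.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    sd = X.std(axis=0)
    zero = np.where(sd == 0)[0]
    if len(zero):
        bad = [expr.samples[i] for i in zero]
        raise ValueError(f"zero-variance samples: {bad}")
    r = np.corrcoef(X.T)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    d = np.maximum((d + d.T) / 2.0, 0.0)  # symmetrize against fp noise
    return pd.DataFrame(d, index=expr.samples, columns=expr.samples)


def _hier_labels(dist: np.ndarray, k: int, method: str) -> np.ndarray:
    condensed = squareform(dist, checks=False)
    Z = linkage(condensed, method=method)
    return fcluster(Z, t=k, criterion="maxclust")


def consensus_cluster(expr: ExpressionMatrix, k_range: Sequence[int] = range(2, 11),
                      n_resamples: int = 1000, subsample_frac: float = 0.8,
                      seed: int = 0, linkage_method: str = "average",
                      delta_threshold: float = 0.1,
                      gap_threshold: float = 0.5) -> ConsensusResult:
    """Run the full consensus-clustering procedure over ``k_range``.

    Deterministic given ``seed``.  ``subsample_frac`` = 1 with a single
    resample degenerates to plain hierarchical clustering (consensus values
    exactly 0/1).
    """
    k_range = sorted(set(int(k) for k in k_range))
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")
    if not (0 < subsample_frac <= 1):
        raise ValueError("subsample_frac must be in (0, 1]")
    dist = pearson_distance(expr).to_numpy()
    n = dist.shape[0]
    n_sub = max(2, int(np.floor(subsample_frac * n)))
    if max(k_range) > n_sub:
        raise ValueError(f"k={max(k_range)} exceeds subsample size {n_sub}")

    rng = np.random.default_rng(seed)
    consensus: dict[int, np.ndarray] = {}
    assignments: dict[int, pd.Series] = {}
    for k in k_range:
        co_cluster = np.zeros((n, n))
        co_sampled = np.zeros((n, n))
        for _ in range(n_resamples):
            if subsample_frac < 1:
                idx = np.sort(rng.choice(n, size=n_sub, replace=False))
            else:
                idx = np.arange(n)
            labels = _hier_labels(dist[np.ix_(idx, idx)], k, linkage_method)
            same = labels[:, None] == labels[None, :]
            co_cluster[np.ix_(idx, idx)] += same
            co_sampled[np.ix_(idx, idx)] += 1
        with np.errstate(invalid="ignore", divide="ignore"):
            M = np.where(co_sampled > 0, co_cluster / co_sampled, 0.0)
        np.fill_diagonal(M, 1.0)
        M = (M + M.T) / 2.0
        consensus[k] = M
        labels_final = _hier_labels(1.0 - M, k, linkage_method)
        assignments[k] = pd.Series(labels_final, index=expr.samples)

    cdf, area = {}, {}
    grid = np.linspace(0, 1, 101)
    for k in k_range:
        vals = consensus[k][np.triu_indices(n, k=1)]
        ecdf = np.searchsorted(np.sort(vals), grid, side="right") / len(vals)
        cdf[k] = (grid, ecdf)
        area[k] = float(np.trapezoid(ecdf, grid))

    delta_area: dict[int, float] = {}
    for i, k in enumerate(k_range):
        if i == 0:
            delta_area[k] = area[k]
        else:
            prev = area[k_range[i - 1]]
            delta_area[k] = (area[k] - prev) / prev if prev > 0 else 0.0

    gap = {k: _consensus_gap(consensus[k], assignments[k].to_numpy()) for k in k_range}
    result = ConsensusResult(
        samples=expr.samples, k_range=k_range, consensus=consensus,
        assignments=assignments, cdf=cdf, area=area, delta_area=delta_area,
        chosen_k=0, low_confidence=False, consensus_gap=gap, rng_seed=seed,
        linkage_method=linkage_method)
    result.chosen_k = (k_range[0] if len(k_range) == 1
                       else select_k(result, delta_threshold=delta_threshold))
    result.low_confidence = gap[result.chosen_k] < gap_threshold
    return result


def _consensus_gap(M: np.ndarray, labels: np.ndarray) -> float:
    """Mean within-cluster minus mean between-cluster consensus (off-diagonal)."""
    n = len(labels)
    iu = np.triu_indices(n, k=1)
    same = labels[iu[0]] == labels[iu[1]]
    vals = M[iu]
    if same.all():
        return float(vals.mean())
    if not same.any():
        return float(-vals.mean())
    return float(vals[same].mean() - vals[~same].mean())


def select_k(result: ConsensusResult, delta_threshold: float = 0.1) -> int:
    """Choose k by the relative delta-area criterion.

    The CDF area grows sharply while adding clusters still separates real
    structure and flattens once k exceeds it, so the chosen k is the largest
    k (>= 3) whose relative area increase stays above ``delta_threshold``;
    if none does, k = 2.  Full diagnostics remain on the result for manual
    review.
    """
    if len(result.k_range) < 2:
        raise ValueError("need at least two k values to select k")
    chosen = result.k_range[0]
    for k in result.k_range[1:]:
        if result.delta_area[k] >= delta_threshold:
            chosen = k
    return chosen


def pca_project(expr: ExpressionMatrix, n_components: int = 2) -> pd.DataFrame:
    """Column-centered SVD projection of samples; deterministic sign convention.

    Returns samples x components coordinates plus explained-variance ratios
    in ``DataFrame.attrs['explained_variance_ratio']``.  Each component's
    sign is fixed so its largest-magnitude gene loading is positive.
    """
    X = expr.data.to_numpy(float).T  # samples x genes
    Xc = X - X.mean(axis=0, keepdims=True)
    rank = np.linalg.matrix_rank(Xc)
    if n_components > min(X.shape):
        raise ValueError(f"n_components={n_components} exceeds matrix dimensions {X.shape}")
    if n_components > rank:
        raise ValueError(f"n_components={n_components} exceeds rank {rank}")
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    for c in range(n_components):
        lead = np.argmax(np.abs(Vt[c]))
        if Vt[c, lead] < 0:
            Vt[c] *= -1
            U[:, c] *= -1
    coords = U[:, :n_components] * S[:n_components]
    total_var = (S ** 2).sum()
    out = pd.DataFrame(coords, index=expr.samples,
                       columns=[f"PC{i + 1}" for i in range(n_components)])
    out.attrs["explained_variance_ratio"] = (S[:n_components] ** 2 / total_var).tolist()
    return out
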