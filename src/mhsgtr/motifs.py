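"""First-order and triangle-motif (M4) high-order similarity graphs.

The pipeline's high-order signal comes from undirected triangles: two
samples that are adjacent and jointly close many triangles with common
neighbours are likely to share a cluster, and a triangle-weighted graph is
far more robust to spurious edges than raw kernel similarity. Stages:

1. Gaussian-kernel first-order similarity S, s_ij = exp(-||x_i - x_j||^2 / (2 sigma^2)).
2. Median-thresholding into a binary adjacency W01 and a weighted adjacency W.
3. Triangle counting: (WM)_ij = number of common neighbours k completing a
   triangle {i, j, k}; equivalently (W01 @ W01) * W01.
4. Motif similarity M = WM ∘ W (Hadamard), min-max rescaled to [0, 1].
5. Hybrid graph A = eta * S + (1 - eta) * M blending first- and high-order
   information.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "FirstOrderSimilarity",
    "ThresholdedGraph",
    "MotifCountMatrix",
    "HybridGraph",
    "gaussian_similarity",
    "threshold_graph",
    "count_triangle_motifs",
    "motif_weighted_similarity",
    "rescale_motif_similarity",
    "hybrid_similarity",
    "build_hybrid_graph",
    "export_edge_list",
]


@dataclass
class FirstOrderSimilarity:
    values: np.ndarray  # N x N, symmetric, unit diagonal, entries in (0, 1]
    bandwidth: float


@dataclass
class ThresholdedGraph:
    binary: np.ndarray    # 0/1, symmetric, zero diagonal
    weighted: np.ndarray  # s_ij where retained, else 0
    threshold: float


@dataclass
class MotifCountMatrix:
    values: np.ndarray  # nonnegative integer counts, symmetric, zero diagonal
    triangle_count: int


@dataclass
class HybridGraph:
    first_order: np.ndarray
    motif_sim: np.ndarray  # rescaled to [0, 1]
    hybrid: np.ndarray
    eta: float


def gaussian_similarity(X: np.ndarray, sigma: float | str = "auto"
                        ) -> FirstOrderSimilarity:
    """Pairwise Gaussian-kernel similarity between sample rows of X.

    ``sigma="auto"`` uses the median pairwise Euclidean distance, a
    scale-free default consistent with the median edge threshold.
    """
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("X must be a 2-D matrix with at least 2 samples")
    d = pdist(X, metric="euclidean")
    if sigma == "auto":
        sigma = float(np.median(d))
        if sigma <= 0:
            sigma = 1.0  # all points coincide; any bandwidth gives S = 1
    sigma = float(sigma)
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    S = squareform(np.exp(-(d ** 2) / (2 * sigma ** 2)))
    np.fill_diagonal(S, 1.0)
    return FirstOrderSimilarity(S, sigma)


def threshold_graph(S: FirstOrderSimilarity) -> ThresholdedGraph:
    """Median-threshold S into binary and weighted adjacency matrices.

    The threshold is the median of the off-diagonal upper-triangle entries
    (the unit diagonal is not an inter-sample similarity and would inflate
    it). Edges with s_ij >= threshold are retained, ties included.
    """
    vals = S.values
    n = vals.shape[0]
    if n < 3:
        warnings.warn("fewer than 3 samples: no triangles possible downstream")
    eps = float(np.median(vals[np.triu_indices(n, k=1)]))
    binary = (vals >= eps).astype(np.int64)
    np.fill_diagonal(binary, 0)
    weighted = np.where(binary == 1, vals, 0.0)
    return ThresholdedGraph(binary, weighted, eps)


def count_triangle_motifs(W01: np.ndarray) -> MotifCountMatrix:
    """Count, per adjacent pair, the triangles (motif M4) they share.

    (WM)_ij = #{k : (i,j), (i,k), (j,k) all edges}. Since the count of
    common neighbours of i and j is (W01^2)_ij, restricting to existing
    edges gives WM = (W01 @ W01) * W01. Each triangle contributes 1 to each
    of its three (unordered) pairs, so sum_{i<j} (WM)_ij = 3 |T|.
    """
    W01 = np.asarray(W01)
    if W01.ndim != 2 or W01.shape[0] != W01.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.array_equal(W01, W01.T):
        raise ValueError("adjacency must be symmetric")
    if np.any(np.diag(W01) != 0):
        raise ValueError("adjacency must have zero diagonal")
    if not np.all(np.isin(W01, [0, 1])):
        raise ValueError("adjacency must be binary")
    A = W01.astype(np.int64)
    WM = (A @ A) * A
    np.fill_diagonal(WM, 0)
    return MotifCountMatrix(WM, int(WM.sum() // 6))


def motif_weighted_similarity(WM: MotifCountMatrix | np.ndarray,
                              W: np.ndarray) -> np.ndarray:
    """Hadamard product of triangle counts with retained edge weights."""
    counts = WM.values if isinstance(WM, MotifCountMatrix) else np.asarray(WM)
    W = np.asarray(W)
    if counts.shape != W.shape:
        raise ValueError(f"shape mismatch: {counts.shape} vs {W.shape}")
    return counts * W


def rescale_motif_similarity(M: np.ndarray) -> np.ndarray:
    """Min-max rescale the (unbounded) motif similarity to [0, 1]."""
    lo, hi = float(M.min()), float(M.max())
    if hi == lo:
        return np.zeros_like(M)
    return (M - lo) / (hi - lo)


def hybrid_similarity(S: np.ndarray, M: np.ndarray, eta: float) -> HybridGraph:
    """Convex blend A = eta*S + (1-eta)*M of first-order and motif graphs.

    M is min-max rescaled to [0, 1] first so eta is a meaningful convex
    weight (raw triangle-weighted entries are unbounded counts).
    """
    if not 0.0 <= eta <= 1.0:
        raise ValueError("eta must lie in [0, 1]")
    S = np.asarray(S, dtype=np.float64)
    M = np.asarray(M, dtype=np.float64)
    if S.shape != M.shape:
        raise ValueError(f"shape mismatch: {S.shape} vs {M.shape}")
    Mr = rescale_motif_similarity(M)
    return HybridGraph(S, Mr, eta * S + (1 - eta) * Mr, eta)


def build_hybrid_graph(X: np.ndarray, sigma: float | str = "auto",
                       eta: float = 0.5) -> HybridGraph:
    """Full Stage-2 chain for one view's raw data matrix X."""
    S = gaussian_similarity(X, sigma)
    tg = threshold_graph(S)
    wm = count_triangle_motifs(tg.binary)
    M = motif_weighted_similarity(wm, tg.weighted)
    return hybrid_similarity(S.values, M, eta)


def export_edge_list(graph: np.ndarray, path: str, sep: str = "\t") -> None:
    """Write the upper-triangle nonzero entries as an `i j weight` list."""
    graph = np.asarray(graph)
    ii, jj = np.triu_indices(graph.shape[0], k=1)
    with open(path, "w") as fh:
        fh.write(sep.join(["i", "j", "weight"]) + "\n")
        for i, j in zip(ii, jj):
            if graph[i, j] != 0:
                fh.write(sep.join([str(i), str(j), repr(float(graph[i, j]))]) + "\n")
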