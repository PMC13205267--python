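"""Attention-weighted consensus graph fusion and its self-training target.

Per-sample omics weights come from a single-layer attention map: the
per-omics graphs are concatenated column-wise, linearly transformed by a
trainable (N*V) x V weight matrix (initialised all-ones), passed through a
LeakyReLU and softmax-normalised across omics, so each sample's V weights
lie on the simplex. The fused graph CF row-scales each C^v by its sample's
weight and sums. CF is then normalised (f1) into a consensus similarity
S_cons with unit diagonal and unit off-diagonal row sums (for symmetric CF),
from which the sharpened DEC-style target distribution P (f2) and the KL
refinement term are computed.

NumPy reference implementations live here; the training loop mirrors them
with autodiff tensors (unit tests pin the two routes together).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "AttentionState",
    "ConsensusGraph",
    "TargetDistribution",
    "init_attention_matrix",
    "attention_weights",
    "fuse_graphs",
    "normalize_f1",
    "target_distribution_f2",
    "kl_refinement",
]


@dataclass
class AttentionState:
    concat: np.ndarray         # N x (N*V)
    weight_matrix: np.ndarray  # (N*V) x V
    weights: np.ndarray        # M_att, N x V rows on the simplex


@dataclass
class ConsensusGraph:
    fused: np.ndarray       # CF
    normalized: np.ndarray  # S_cons = f1(CF)
    row_sums: np.ndarray    # off-diagonal row sums of CF


@dataclass
class TargetDistribution:
    P: np.ndarray  # rows sum to 1


def init_attention_matrix(n_samples: int, n_views: int) -> np.ndarray:
    """All-ones initial attention weight matrix of shape (N*V) x V."""
    return np.ones((n_samples * n_views, n_views))


def _leaky_relu(x: np.ndarray, slope: float) -> np.ndarray:
    return np.where(x > 0, x, slope * x)


def attention_weights(graphs: list[np.ndarray], weight_matrix: np.ndarray,
                      negative_slope: float = 0.01) -> AttentionState:
    """M_att = softmax(LeakyReLU(concat(C^1..C^V) @ W)) across omics per row."""
    if not graphs:
        raise ValueError("need at least one graph")
    n = graphs[0].shape[0]
    if any(g.shape != (n, n) for g in graphs):
        raise ValueError("graphs must be square with equal shapes")
    V = len(graphs)
    concat = np.concatenate(graphs, axis=1)
    if weight_matrix.shape != (n * V, V):
        raise ValueError(f"weight matrix must be {(n * V, V)}, "
                         f"got {weight_matrix.shape}")
    logits = _leaky_relu(concat @ weight_matrix, negative_slope)
    logits = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(logits)
    weights = e / e.sum(axis=1, keepdims=True)
    return AttentionState(concat, weight_matrix, weights)


def fuse_graphs(graphs: list[np.ndarray], M_att: np.ndarray) -> np.ndarray:
    """CF = sum_v (m_v 1^T) ∘ C^v: row i of C^v scaled by weight M_att[i, v]."""
    n = graphs[0].shape[0]
    if M_att.shape != (n, len(graphs)):
        raise ValueError("attention weights must be N x V")
    CF = np.zeros((n, n))
    for v, g in enumerate(graphs):
        CF += M_att[:, v:v + 1] * g
    return CF


def normalize_f1(CF: np.ndarray, clip_negative: bool = True) -> ConsensusGraph:
    """f1 normalisation: s_ij = (c_ij + c_ji) / (2 c_sum_i), s_ii = 1.

    c_sum_i is the sum of the off-diagonal entries of row i of CF. Negative
    off-diagonal entries (possible for raw self-expressive coefficients) are
    clipped to zero first.
    """
    CF = np.array(CF, dtype=np.float64)
    n = CF.shape[0]
    if clip_negative:
        CF = np.maximum(CF, 0.0)
    off = CF - np.diag(np.diag(CF))
    row_sums = off.sum(axis=1)
    if np.any(row_sums <= 0):
        bad = int(np.argmax(row_sums <= 0))
        raise ValueError(f"sample index {bad}: all-zero off-diagonal row in CF")
    S = (off + off.T) / (2.0 * row_sums[:, None])
    np.fill_diagonal(S, 1.0)
    return ConsensusGraph(CF, S, row_sums)


def target_distribution_f2(S_cons: np.ndarray) -> TargetDistribution:
    """Sharpened self-training target p_ij = (s_ij^2/f_j) / sum_j'(s_ij'^2/f_j').

    f_j is the column mass of S_cons; squaring sharpens confident
    similarities while the 1/f_j factor guards against mass concentrating on
    a few columns.
    """
    S = np.asarray(S_cons, dtype=np.float64)
    if np.any(S < 0):
        raise ValueError("S_cons must be nonnegative")
    f = S.sum(axis=0)
    if np.any(f <= 0):
        raise ValueError("zero column mass in S_cons")
    Q = S ** 2 / f[None, :]
    denom = Q.sum(axis=1, keepdims=True)
    if np.any(denom <= 0):
        raise ValueError("zero row in sharpened similarity")
    return TargetDistribution(Q / denom)


def kl_refinement(P: TargetDistribution | np.ndarray,
                  S_cons: np.ndarray) -> float:
    """KL(P || row-normalised S_cons) with the convention 0*log 0 = 0."""
    Pm = P.P if isinstance(P, TargetDistribution) else np.asarray(P)
    S = np.asarray(S_cons, dtype=np.float64)
    Sn = S / S.sum(axis=1, keepdims=True)
    mask = Pm > 0
    if np.any(Sn[mask] <= 0):
        raise ValueError("support violation: s_ij = 0 where p_ij > 0")
    return float(np.sum(Pm[mask] * np.log(Pm[mask] / Sn[mask])))
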