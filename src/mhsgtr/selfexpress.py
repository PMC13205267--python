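"""Sparse autoencoder with a linear self-expressive layer, per omics view.

Each view's N x d_v matrix is encoded by a two-hidden-layer perceptron
(ReLU hidden activations, linear output) into an N x p2 latent code Z. A
fully connected linear layer *between* encoder and decoder with an N x N
coefficient matrix C (diagonal constrained to zero to rule out the trivial
C = I solution) realises the self-expressive assumption Z ~= C Z: each
sample's code is a linear combination of the other samples', and C doubles
as an affinity graph. The decoder reconstructs from Z during pretraining
and from C Z during joint training.

Loss terms (per view):
  reconstruction      (1/2n) ||X - Xrec||_F^2
  row sparsity        alpha * ||W1||_{2,1}   (first-layer weights; shrinks
                      whole input features, i.e. feature selection)
  self-expression     lambda1 ||Z - C Z||_F^2 + lambda2 ||C||_F^2
  high-order align    lambda3 ||A - C||_F^2  (A = hybrid motif graph)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._autograd import Tensor

__all__ = [
    "LossWeights",
    "EncoderState",
    "l21_norm",
    "reconstruction_loss",
    "self_expression_loss",
    "high_order_alignment_loss",
    "encode_decode",
]


@dataclass
class LossWeights:
    alpha: float = 0.01
    lambda1: float = 1.0
    lambda2: float = 0.1
    lambda3: float = 1.0
    beta: float = 0.1
    n: int | None = None  # sample count in the 1/(2n) factor; None -> N of view

    def __post_init__(self):
        for name in ("alpha", "lambda1", "lambda2", "lambda3", "beta"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


# ---------------------------------------------------------------------------
# plain-NumPy loss primitives (reference forms; the training loop rebuilds
# them with autodiff tensors and tests pin the two routes together)
# ---------------------------------------------------------------------------

def l21_norm(W: np.ndarray) -> float:
    """Sum of Euclidean norms of the rows of W (row-wise sparsity penalty)."""
    W = np.asarray(W, dtype=np.float64)
    if not np.all(np.isfinite(W)):
        raise ValueError("matrix contains non-finite entries")
    return float(np.sqrt((W ** 2).sum(axis=1)).sum())


def reconstruction_loss(X: np.ndarray, Xrec: np.ndarray, n: int) -> float:
    """(1/2n) * squared Frobenius reconstruction error."""
    return float(((np.asarray(X) - np.asarray(Xrec)) ** 2).sum() / (2.0 * n))


def self_expression_loss(Z: np.ndarray, C: np.ndarray,
                         l1: float, l2: float) -> float:
    """lambda1 ||Z - C Z||_F^2 + lambda2 ||C||_F^2."""
    Z, C = np.asarray(Z), np.asarray(C)
    return float(l1 * ((Z - C @ Z) ** 2).sum() + l2 * (C ** 2).sum())


def high_order_alignment_loss(A: np.ndarray, C: np.ndarray,
                              l3: float) -> float:
    """lambda3 ||A - C||_F^2, pulling the affinity toward the hybrid graph."""
    A, C = np.asarray(A), np.asarray(C)
    if A.shape != C.shape:
        raise ValueError(f"shape mismatch: {A.shape} vs {C.shape}")
    return float(l3 * ((A - C) ** 2).sum())


# ---------------------------------------------------------------------------
# trainable per-view network
# ---------------------------------------------------------------------------

class EncoderState:
    """Weights of one view's autoencoder + self-expressive layer.

    Hidden dims default to the full-scale 1024/512 configuration; tests and
    desk-scale runs pass smaller dims. The diagonal of C is masked out in
    every forward pass, so gradients never move it off zero.
    """

    def __init__(self, n_samples: int, n_features: int,
                 hidden_dims: tuple[int, int] = (1024, 512),
                 rng: np.random.Generator | None = None,
                 C_init: np.ndarray | None = None):
        rng = rng if rng is not None else np.random.default_rng(0)
        p1, p2 = hidden_dims
        d = n_features

        def glorot(fan_in, fan_out):
            bound = np.sqrt(6.0 / (fan_in + fan_out))
            return Tensor(rng.uniform(-bound, bound, (fan_in, fan_out)),
                          requires_grad=True)

        self.n_samples, self.n_features = n_samples, d
        self.hidden_dims = (p1, p2)
        self.W1 = glorot(d, p1)
        self.b1 = Tensor(np.zeros(p1), requires_grad=True)
        self.W2 = glorot(p1, p2)
        self.b2 = Tensor(np.zeros(p2), requires_grad=True)
        self.W3 = glorot(p2, p1)
        self.b3 = Tensor(np.zeros(p1), requires_grad=True)
        self.W4 = glorot(p1, d)
        self.b4 = Tensor(np.zeros(d), requires_grad=True)
        # self-expressive coefficients: warm-started at the view's hybrid
        # graph when available (the alignment term anchors C there), else a
        # small random matrix; zero diagonal enforced via mask
        if C_init is not None:
            if C_init.shape != (n_samples, n_samples):
                raise ValueError("C_init must be N x N")
            self.C = Tensor(np.array(C_init, dtype=np.float64),
                            requires_grad=True)
        else:
            self.C = Tensor(rng.normal(0.0, 1e-4, (n_samples, n_samples)),
                            requires_grad=True)
        self._diag_mask = Tensor(1.0 - np.eye(n_samples))

    @property
    def params(self) -> list[Tensor]:
        return [self.W1, self.b1, self.W2, self.b2,
                self.W3, self.b3, self.W4, self.b4, self.C]

    @property
    def ae_params(self) -> list[Tensor]:
        return [self.W1, self.b1, self.W2, self.b2,
                self.W3, self.b3, self.W4, self.b4]

    def masked_C(self) -> Tensor:
        return self.C * self._diag_mask

    def encode(self, X: Tensor) -> Tensor:
        h = (X @ self.W1 + self.b1).relu()
        return h @ self.W2 + self.b2  # linear latent layer

    def decode(self, Z: Tensor) -> Tensor:
        h = (Z @ self.W3 + self.b3).relu()
        return h @ self.W4 + self.b4

    def symmetrized_graph(self) -> np.ndarray:
        """(|C| + |C^T|)/2: the nonnegative symmetric affinity used downstream."""
        C = self.C.data * self._diag_mask.data
        return (np.abs(C) + np.abs(C.T)) / 2.0

    def state_dict(self) -> dict[str, np.ndarray]:
        names = ["W1", "b1", "W2", "b2", "W3", "b3", "W4", "b4", "C"]
        return {k: getattr(self, k).data.copy() for k in names}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, v in state.items():
            getattr(self, k).data[...] = v


def encode_decode(X: np.ndarray, state: EncoderState,
                  use_self_expression: bool = True
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Deterministic forward pass; returns (Z, Xrec, C Z).

    During joint training the decoder consumes the self-expressed code C Z;
    during pretraining it consumes Z directly.
    """
    X = np.asarray(X, dtype=np.float64)
    if X.shape != (state.n_samples, state.n_features):
        raise ValueError(f"X must be {(state.n_samples, state.n_features)}, "
                         f"got {X.shape}")
    Xt = Tensor(X)
    Z = state.encode(Xt)
    CZ = state.masked_C() @ Z
    Xrec = state.decode(CZ if use_self_expression else Z)
    return Z.data, Xrec.data, CZ.data
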