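"""t-SVD tensor nuclear norm and its proximal operator for graph stacks.

The per-omics affinity graphs C^1..C^V are stacked into an N x N x V tensor
and rotated to N x V x N so that the omics mode becomes a matrix dimension
of the frontal slices; a low tubal rank of the rotated tensor then couples
structure *across* omics. The tensor nuclear norm (TNN) used here is the
Fourier-domain definition: FFT along the third mode, then the mean over
transformed frontal slices of their matrix nuclear norms. With one slice it
reduces exactly to the matrix nuclear norm. The proximal map of tau*TNN is
slice-wise singular-value soft-thresholding in the Fourier domain (by
n3*tau, consistent with the 1/n3 norm scaling).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["GraphTensor", "stack_and_rotate", "unrotate",
           "tensor_nuclear_norm", "tsvt_prox", "slice_spectra"]


@dataclass
class GraphTensor:
    values: np.ndarray  # N x N x V if not rotated, N x V x N if rotated
    rotated: bool

    @property
    def n_slices(self) -> int:
        return self.values.shape[2]


def stack_and_rotate(graphs: list[np.ndarray]) -> GraphTensor:
    """Stack N x N graphs into T[i,j,v] = C^v[i,j], rotated to R[i,v,j].

    The rotation (i, j, v) -> (i, v, j) is a lossless entry permutation;
    :func:`unrotate` inverts it exactly.
    """
    if not graphs:
        raise ValueError("need at least one graph")
    shape = graphs[0].shape
    if any(g.shape != shape for g in graphs) or shape[0] != shape[1]:
        raise ValueError("graphs must all be square with equal shapes")
    native = np.stack(graphs, axis=2)       # N x N x V
    rotated = native.transpose(0, 2, 1)     # N x V x N
    return GraphTensor(np.ascontiguousarray(rotated), rotated=True)


def unrotate(T: GraphTensor) -> list[np.ndarray]:
    """Recover the original graph list from a rotated tensor."""
    if not T.rotated:
        return [T.values[:, :, v] for v in range(T.values.shape[2])]
    native = T.values.transpose(0, 2, 1)    # back to N x N x V
    return [np.ascontiguousarray(native[:, :, v])
            for v in range(native.shape[2])]


def _as_rotated_array(T) -> np.ndarray:
    if isinstance(T, GraphTensor):
        if not T.rotated:
            raise ValueError("tensor must be in rotated form")
        return T.values
    return np.asarray(T, dtype=np.float64)


def tensor_nuclear_norm(T) -> float:
    """TNN = (1/n3) * sum over FFT frontal slices of their nuclear norms."""
    A = _as_rotated_array(T)
    if not np.all(np.isfinite(A)):
        raise ValueError("tensor contains non-finite entries")
    n3 = A.shape[2]
    F = np.fft.fft(A, axis=2)
    total = 0.0
    for t in range(n3):
        total += np.linalg.svd(F[:, :, t], compute_uv=False).sum()
    return float(total / n3)


def tsvt_prox(T, tau: float) -> GraphTensor:
    """Exact proximal map of tau * TNN (tensor singular-value thresholding).

    Minimises tau*||X||_* + 0.5*||X - T||_F^2. By Parseval for the
    unnormalised DFT, ||X - T||_F^2 = (1/n3)*sum_t ||Xhat_t - That_t||_F^2,
    so the objective separates over Fourier slices as
    (1/n3)*sum_t [tau*||Xhat_t||_* + 0.5*||Xhat_t - That_t||_F^2] and each
    slice's singular values are soft-thresholded by tau. Conjugate symmetry
    of the FFT of a real tensor is preserved, so the output is exactly real.
    """
    if tau < 0:
        raise ValueError("tau must be nonnegative")
    A = _as_rotated_array(T)
    n3 = A.shape[2]
    F = np.fft.fft(A, axis=2)
    out = np.empty_like(F)
    half = n3 // 2 + 1
    for t in range(half):
        U, s, Vt = np.linalg.svd(F[:, :, t], full_matrices=False)
        s = np.maximum(s - tau, 0.0)
        out[:, :, t] = (U * s) @ Vt
    for t in range(half, n3):  # conjugate symmetry: slice t = conj(slice n3-t)
        out[:, :, t] = np.conj(out[:, :, n3 - t])
    X = np.fft.ifft(out, axis=2)
    imag_residue = float(np.abs(X.imag).max()) if X.size else 0.0
    if imag_residue > 1e-9:
        raise FloatingPointError(
            f"prox output not real (imaginary residue {imag_residue:.2e})")
    return GraphTensor(np.ascontiguousarray(X.real), rotated=True)


def slice_spectra(T) -> np.ndarray:
    """Per-Fourier-slice singular-value spectra (rows = slices), for debugging."""
    A = _as_rotated_array(T)
    F = np.fft.fft(A, axis=2)
    return np.stack([np.linalg.svd(F[:, :, t], compute_uv=False)
                     for t in range(A.shape[2])])
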