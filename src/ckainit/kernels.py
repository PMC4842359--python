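"""Kernel matrices, centering and the centered kernel alignment coefficient.

Centered kernel alignment (CKA) measures the similarity between the
geometries induced by two Gram matrices ``K`` and ``B`` as the normalized
Frobenius inner product of their doubly centered versions:

.. math::

    \\rho(K, B) = \\frac{\\langle HKH,\\, HBH \\rangle_F}
                       {\\lVert HKH \\rVert_F\\, \\lVert HBH \\rVert_F},
    \\qquad H = I - n^{-1}\\mathbf{1}\\mathbf{1}^\\top .

For positive semidefinite inputs ``rho`` lies in ``[0, 1]``; ``rho = 1``
holds exactly when the centered matrices are proportional (Cauchy-Schwarz
equality). The centering matrix ``H`` is never materialized: ``HKH`` is
computed by subtracting row, column and grand means, which is O(n^2).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "DegenerateKernelError",
    "center_kernel",
    "label_kernel",
    "gaussian_kernel",
    "cka",
]


class DegenerateKernelError(ValueError):
    """Raised when a kernel is constant, so its centered version vanishes."""


def _as_square(K: np.ndarray, name: str = "K") -> np.ndarray:
    K = np.asarray(K, dtype=float)
    if K.ndim != 2 or K.shape[0] != K.shape[1]:
        raise ValueError(f"{name} must be a square matrix, got shape {K.shape}")
    return K


def center_kernel(K: np.ndarray) -> np.ndarray:
    """Return the doubly centered kernel ``HKH`` without materializing ``H``.

    Uses the identity ``(HKH)_ij = K_ij - rowmean_i - colmean_j + grandmean``.
    Rows and columns of the result each sum to zero (within round-off), and
    the operation is idempotent.
    """
    K = _as_square(K)
    row = K.mean(axis=1, keepdims=True)
    col = K.mean(axis=0, keepdims=True)
    return K - row - col + K.mean()


def label_kernel(t: np.ndarray) -> np.ndarray:
    """Binary label kernel ``B`` with ``b_ij = 1`` iff samples i, j share a class.

    ``B`` is symmetric with unit diagonal and, after sorting samples by label,
    block diagonal with one all-ones block per class.
    """
    t = np.asarray(t).ravel()
    if t.size == 0:
        raise ValueError("label vector is empty")
    return (t[:, None] == t[None, :]).astype(float)


def gaussian_kernel(sq_dists: np.ndarray, sigma: float = 1.0) -> np.ndarray:
    """Elementwise Gaussian kernel ``k_ij = exp(-d2_ij / (2 sigma^2))``.

    Parameters
    ----------
    sq_dists
        Symmetric matrix of squared distances with zero diagonal.
    sigma
        Kernel bandwidth, > 0. The default of 1 is deliberate: when the
        distances come from a learned linear map the scale of the map absorbs
        the bandwidth, so a free ``sigma`` would be redundant.
    """
    if not np.isfinite(sigma) or sigma <= 0:
        raise ValueError(f"sigma must be a positive real, got {sigma!r}")
    sq_dists = _as_square(sq_dists, "sq_dists")
    if np.any(sq_dists < 0):
        raise ValueError("squared distances must be nonnegative")
    return np.exp(sq_dists / (-2.0 * sigma * sigma))


def cka(K: np.ndarray, B: np.ndarray) -> float:
    """Centered kernel alignment ``rho(K, B)`` in ``[0, 1]`` for PSD inputs.

    Raises
    ------
    DegenerateKernelError
        If either kernel is constant (its centered version has zero
        Frobenius norm), which leaves the alignment undefined.
    """
    K = _as_square(K)
    B = _as_square(B, "B")
    Kc = center_kernel(K)
    Bc = center_kernel(B)
    if Kc.shape != Bc.shape:
        raise ValueError(f"kernel shapes differ: {Kc.shape} vs {Bc.shape}")
    nk = float(np.linalg.norm(Kc))
    nb = float(np.linalg.norm(Bc))
    scale = max(abs(K).max(initial=0.0), abs(B).max(initial=0.0), 1.0)
    if nk <= 1e-12 * scale * Kc.shape[0] or nb <= 1e-12 * scale * Bc.shape[0]:
        raise DegenerateKernelError(
            "centered kernel has (near-)zero Frobenius norm; a constant kernel "
            "carries no alignment information"
        )
    rho = float(np.vdot(Kc, Bc)) / (nk * nb)
    # round-off guards only: PSD inputs give rho in [0, 1] analytically
    if -1e-12 <= rho < 0.0:
        rho = 0.0
    return min(rho, 1.0)
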