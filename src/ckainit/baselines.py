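"""Unsupervised pretraining baselines: PCA loadings and a shallow autoencoder.

Both return an m1 x D matrix with the same shape contract as the
alignment-learned projection, so any of the three can initialize the first
layer of the classifier interchangeably.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import sigmoid

__all__ = ["AENConfig", "pca_projection", "aen_fit"]


@dataclass
class AENConfig:
    """Hyperparameters of the single-hidden-layer autoencoder.

    Sigmoid encoder, linear decoder, untied weights, mean-squared
    reconstruction loss, seeded minibatch SGD.
    """

    m1: int = 14
    epochs: int = 200
    learning_rate: float = 0.05
    batch_size: int = 32
    seed: int = 0
    tied_weights: bool = False

    def __post_init__(self) -> None:
        if self.m1 < 1 or self.epochs < 1 or self.batch_size < 1:
            raise ValueError("m1/epochs/batch_size must be positive")
        if not self.learning_rate > 0:
            raise ValueError("learning_rate must be > 0")


def pca_projection(X: np.ndarray, m1: int) -> np.ndarray:
    """Top-m1 principal axes of ``X`` as rows (unit norm, descending variance).

    ``X`` is expected standardized. Signs are fixed so each row's
    largest-magnitude entry is positive, making the result reproducible
    across BLAS builds.
    """
    X = np.asarray(X, dtype=float)
    n, d = X.shape
    if not 1 <= m1 <= min(n - 1, d):
        raise ValueError(f"m1 must lie in 1..min(N-1, D) = {min(n - 1, d)}, got {m1}")
    Xc = X - X.mean(axis=0, keepdims=True)
    _, _, Vt = np.linalg.svd(Xc, full_matrices=False)
    W = Vt[:m1].copy()
    for row in W:
        if row[np.argmax(np.abs(row))] < 0:
            row *= -1.0
    return W


def aen_fit(
    X: np.ndarray, cfg: AENConfig | None = None, return_history: bool = False
) -> np.ndarray | tuple[np.ndarray, list[float]]:
    """Train the autoencoder on ``X`` and return the m1 x D encoder weights.

    The decoder is linear, so with enough capacity the encoder spans the
    same subspace PCA finds, but the sigmoid encoder matches the hidden
    layer it will initialize. With ``return_history`` the per-epoch mean
    reconstruction MSE is returned alongside the weights.
    """
    cfg = cfg if cfg is not None else AENConfig()
    X = np.asarray(X, dtype=float)
    n, d = X.shape
    if cfg.m1 > d:
        raise ValueError(f"m1={cfg.m1} exceeds the feature count D={d}")
    rng = np.random.default_rng(cfg.seed)
    r = 1.0 / np.sqrt(d)
    W_enc = rng.uniform(-r, r, size=(cfg.m1, d))
    b_enc = rng.uniform(-r, r, size=cfg.m1)
    r2 = 1.0 / np.sqrt(cfg.m1)
    W_dec = W_enc.T.copy() if cfg.tied_weights else rng.uniform(-r2, r2, size=(d, cfg.m1))
    b_dec = np.zeros(d)

    lr = cfg.learning_rate
    history: list[float] = []
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            batch = order[start : start + cfg.batch_size]
            Xb = X[batch]
            H = sigmoid(Xb @ W_enc.T + b_enc)
            R = H @ W_dec.T + b_dec
            E = R - Xb  # d(MSE)/dR up to 2/(B*D)
            loss = float(np.mean(E * E))
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"autoencoder diverged (non-finite reconstruction loss) at "
                    f"epoch {epoch}; reduce the learning rate"
                )
            epoch_loss += loss * len(batch)
            scale = 2.0 / E.size
            gW_dec = scale * E.T @ H
            gb_dec = scale * E.sum(axis=0)
            dH = scale * E @ W_dec * (2.0 * H * (1.0 - H))
            gW_enc = dH.T @ Xb
            gb_enc = dH.sum(axis=0)
            if cfg.tied_weights:
                gW_enc = gW_enc + gW_dec.T
            W_enc -= lr * gW_enc
            b_enc -= lr * gb_enc
            if cfg.tied_weights:
                W_dec = W_enc.T
            else:
                W_dec -= lr * gW_dec
            b_dec -= lr * gb_dec
        history.append(epoch_loss / n)
    return (W_enc, history) if return_history else W_enc
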