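"""Feedforward softmax classifier trained by backpropagation.

The network is a stack of affine maps with a saturating nonlinearity on the
hidden layers, ``h^l = phi(b^l + W^l h^{l-1})`` with ``h^0 = x``, and a
softmax output interpreted as class posteriors ``P(t = c | x)``. The
nonlinearity is the tanh-form sigmoid ``phi(z) = (tanh(z) + 1) / 2``
(equivalently the logistic function of ``2z``), whose derivative is
``2 phi (1 - phi)``. Training minimizes the mean negative log-likelihood of
the target class by plain minibatch SGD.

The point of the surrounding package is the *initialization* of the first
layer: ``init_network`` accepts a strategy name — ``random``, ``pca``,
``aen`` (autoencoder) or ``cka`` (alignment-maximizing projection) — and
places the corresponding m1 x D projection matrix in the first layer, while
biases and the output layer are always drawn randomly from a seeded
uniform(-r, r) with r = 1/sqrt(fan_in).

Labels are 1-based ``{1..C}`` at every public interface and shifted to
0-based indices only internally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "NetworkParams",
    "TrainConfig",
    "sigmoid",
    "forward",
    "predict",
    "nll_loss",
    "init_network",
    "train",
]

PROB_FLOOR = 1e-12


@dataclass
class NetworkParams:
    """Ordered per-layer parameters ``(W^l, b^l)`` of a feedforward net."""

    layers: list[tuple[np.ndarray, np.ndarray]]

    def __post_init__(self) -> None:
        if len(self.layers) < 2:
            raise ValueError("need at least one hidden layer plus the softmax output")
        for i, (W, b) in enumerate(self.layers):
            if W.ndim != 2 or b.ndim != 1 or W.shape[0] != b.shape[0]:
                raise ValueError(f"layer {i}: W {W.shape} and b {b.shape} disagree")
            if i > 0 and W.shape[1] != self.layers[i - 1][0].shape[0]:
                raise ValueError(
                    f"layer {i} expects {W.shape[1]} inputs but layer {i - 1} "
                    f"emits {self.layers[i - 1][0].shape[0]}"
                )

    @property
    def sizes(self) -> tuple[int, ...]:
        """Layer widths ``(D, m1, ..., C)``."""
        return (self.layers[0][0].shape[1],) + tuple(
            W.shape[0] for W, _ in self.layers
        )

    def copy(self) -> "NetworkParams":
        return NetworkParams([(W.copy(), b.copy()) for W, b in self.layers])


@dataclass
class TrainConfig:
    epochs: int = 300
    batch_size: int = 32
    learning_rate: float = 0.05
    seed: int = 0
    early_stop_patience: int | None = None
    holdout_fraction: float = 0.1  # used only when early stopping is on

    def __post_init__(self) -> None:
        if self.epochs < 0 or self.batch_size < 1 or self.learning_rate < 0:
            raise ValueError("epochs/batch_size/learning_rate out of range")


def sigmoid(z: np.ndarray | float) -> np.ndarray | float:
    """Saturating nonlinearity ``(tanh(z) + 1) / 2``, stable for large |z|."""
    return 0.5 * (np.tanh(z) + 1.0)


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def forward(
    params: NetworkParams, X: np.ndarray
) -> tuple[list[np.ndarray], np.ndarray]:
    """Run the net on ``X`` (N x D, samples in rows).

    Returns the list of activations ``[h^0, h^1, ..., h^{L-1}]`` and the
    softmax output (N x C); every output row is positive and sums to 1.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != params.sizes[0]:
        raise ValueError(
            f"input has {X.shape[1]} features but the network expects "
            f"{params.sizes[0]}"
        )
    acts = [X]
    h = X
    for W, b in params.layers[:-1]:
        h = sigmoid(h @ W.T + b)
        acts.append(h)
    W_out, b_out = params.layers[-1]
    probs = _softmax(h @ W_out.T + b_out)
    return acts, probs


def predict(params: NetworkParams, X: np.ndarray) -> np.ndarray:
    """Most probable 1-based class label per sample."""
    _, probs = forward(params, X)
    return np.argmax(probs, axis=1) + 1


def nll_loss(probs: np.ndarray, t: np.ndarray) -> float:
    """Mean negative log-likelihood ``-log P(t_i | x_i)`` of 1-based targets."""
    probs = np.atleast_2d(np.asarray(probs, dtype=float))
    t = np.asarray(t).ravel()
    if t.shape[0] != probs.shape[0]:
        raise ValueError("probs and t have different lengths")
    if np.any(t < 1) or np.any(t > probs.shape[1]):
        raise ValueError(f"labels must lie in 1..{probs.shape[1]}")
    p = probs[np.arange(t.size), t.astype(int) - 1]
    return float(-np.log(np.maximum(p, PROB_FLOOR)).mean())


def _uniform_init(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    r = 1.0 / np.sqrt(shape[1])
    return rng.uniform(-r, r, size=shape)


def init_network(
    strategy: str,
    X: np.ndarray,
    t: np.ndarray,
    m1: int,
    seed: int = 0,
    n_classes: int | None = None,
    projection: np.ndarray | None = None,
    **strategy_kwargs,
) -> NetworkParams:
    """Build a D-m1-C network with the first layer set by ``strategy``.

    ``X`` should already be standardized. For ``cka``/``pca``/``aen`` the
    corresponding projection is fitted here (keyword arguments are forwarded
    to the fitter) unless a precomputed ``projection`` matrix is supplied.
    Biases and the output layer are always random, seeded by ``seed``.
    """
    X = np.asarray(X, dtype=float)
    t = np.asarray(t).ravel()
    d = X.shape[1]
    C = int(n_classes) if n_classes is not None else int(t.max())
    rng = np.random.default_rng(seed)
    if projection is not None:
        W1 = np.asarray(projection, dtype=float)
        if W1.shape != (m1, d):
            raise ValueError(f"projection shape {W1.shape} != ({m1}, {d})")
    elif strategy == "random":
        W1 = _uniform_init(rng, (m1, d))
    elif strategy == "pca":
        from .baselines import pca_projection

        W1 = pca_projection(X, m1)
    elif strategy == "aen":
        from .baselines import AENConfig, aen_fit

        W1 = aen_fit(X, AENConfig(m1=m1, seed=seed, **strategy_kwargs))
    elif strategy == "cka":
        from .projection import OptimizerConfig, fit_cka_projection

        cfg = OptimizerConfig(seed=seed, **strategy_kwargs)
        W1 = fit_cka_projection(X, t, m1, cfg).W
    else:
        raise ValueError(
            f"unknown initialization strategy {strategy!r}; "
            "expected one of random, pca, aen, cka"
        )
    b1 = rng.uniform(-1.0 / np.sqrt(d), 1.0 / np.sqrt(d), size=m1)
    W2 = _uniform_init(rng, (C, m1))
    b2 = rng.uniform(-1.0 / np.sqrt(m1), 1.0 / np.sqrt(m1), size=C)
    return NetworkParams([(W1, b1), (W2, b2)])


def _backprop(
    params: NetworkParams, X: np.ndarray, t0: np.ndarray
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Gradients of the mean NLL for a batch; ``t0`` is 0-based."""
    acts, probs = forward(params, X)
    n = X.shape[0]
    delta = probs.copy()
    delta[np.arange(n), t0] -= 1.0
    delta /= n
    grads: list[tuple[np.ndarray, np.ndarray]] = []
    for l in range(len(params.layers) - 1, -1, -1):
        W, _ = params.layers[l]
        grads.append((delta.T @ acts[l], delta.sum(axis=0)))
        if l > 0:
            h = acts[l]
            delta = (delta @ W) * (2.0 * h * (1.0 - h))
    grads.reverse()
    return grads


def _stratified_holdout(
    t: np.ndarray, fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    hold: list[int] = []
    for c in np.unique(t):
        idx = np.flatnonzero(t == c)
        rng.shuffle(idx)
        k = max(1, int(round(fraction * idx.size)))
        hold.extend(idx[:k])
    hold_idx = np.sort(np.asarray(hold, dtype=int))
    mask = np.ones(t.size, dtype=bool)
    mask[hold_idx] = False
    return np.flatnonzero(mask), hold_idx


def train(
    params: NetworkParams,
    X: np.ndarray,
    t: np.ndarray,
    cfg: TrainConfig | None = None,
) -> tuple[NetworkParams, list[float]]:
    """Minibatch SGD on the mean NLL; returns new params and per-epoch loss.

    The input ``params`` are not mutated. The recorded history is the mean
    training loss per epoch. With ``early_stop_patience`` set, a seeded
    stratified holdout (``holdout_fraction``) is split off and training
    stops once its loss has not improved for that many epochs, restoring the
    best parameters seen.
    """
    cfg = cfg if cfg is not None else TrainConfig()
    X = np.asarray(X, dtype=float)
    t = np.asarray(t).ravel()
    if np.unique(t).size < 2:
        raise ValueError("training labels must contain at least 2 classes")
    params = params.copy()
    rng = np.random.default_rng(cfg.seed)

    if cfg.early_stop_patience is not None:
        tr_idx, ho_idx = _stratified_holdout(t, cfg.holdout_fraction, rng)
        X_ho, t_ho = X[ho_idx], t[ho_idx]
        X_tr, t_tr = X[tr_idx], t[tr_idx]
    else:
        X_tr, t_tr = X, t
        X_ho = t_ho = None

    t0 = t_tr.astype(int) - 1
    n = X_tr.shape[0]
    history: list[float] = []
    best = (np.inf, params.copy())
    stale = 0
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_losses: list[float] = []
        for start in range(0, n, cfg.batch_size):
            batch = order[start : start + cfg.batch_size]
            Xb, tb = X_tr[batch], t0[batch]
            _, probs = forward(params, Xb)
            loss = nll_loss(probs, tb + 1)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss {loss} at epoch {len(history)}, "
                    f"batch starting {start}; try a smaller learning rate"
                )
            epoch_losses.append(loss * batch.size)
            if cfg.learning_rate > 0:
                grads = _backprop(params, Xb, tb)
                for (W, b), (gW, gb) in zip(params.layers, grads):
                    W -= cfg.learning_rate * gW
                    b -= cfg.learning_rate * gb
        history.append(float(np.sum(epoch_losses) / n))
        if cfg.early_stop_patience is not None:
            _, probs_ho = forward(params, X_ho)
            ho_loss = nll_loss(probs_ho, t_ho)
            if ho_loss < best[0] - 1e-12:
                best = (ho_loss, params.copy())
                stale = 0
            else:
                stale += 1
                if stale >= cfg.early_stop_patience:
                    params = best[1]
                    break
    return params, history
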