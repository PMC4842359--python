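"""Feature standardization on training statistics."""

from __future__ import annotations

import numpy as np

__all__ = ["Scaler", "fit_scaler"]


class Scaler:
    """Per-feature z-scoring with a floor on the standard deviation.

    Fit on training data only; apply the same shift/scale to validation and
    test data so no test statistics leak into the model.
    """

    def __init__(self, mean: np.ndarray, std: np.ndarray):
        self.mean = np.asarray(mean, dtype=float)
        self.std = np.asarray(std, dtype=float)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean) / self.std


def fit_scaler(X: np.ndarray, std_floor: float = 1e-8) -> Scaler:
    X = np.asarray(X, dtype=float)
    std = X.std(axis=0, ddof=0)
    return Scaler(X.mean(axis=0), np.maximum(std, std_floor))
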