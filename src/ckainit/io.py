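"""CSV dataset exchange and JSON serialization of fitted models.

One tabular format everywhere: CSV with a header of feature names plus a
final integer ``label`` column. Models and reports are JSON documents with
matrices stored row-major, so every artifact is a plain text file that
round-trips exactly.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .evaluation import EvaluationReport
from .network import NetworkParams
from .projection import OptimizerConfig, ProjectionModel

__all__ = [
    "read_dataset",
    "write_dataset",
    "save_projection",
    "load_projection",
    "save_network",
    "load_network",
    "save_report",
]


def read_dataset(path) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Read a feature table: (X, labels, feature_names).

    Expects numeric feature columns and a final integer ``label`` column in
    1..C. Malformed cells are reported with their CSV line number.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if "label" not in df.columns:
        raise ValueError(f"{path}: missing required 'label' column")
    feature_cols = [c for c in df.columns if c != "label"]
    if not feature_cols:
        raise ValueError(f"{path}: no feature columns found")
    for col in feature_cols:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[numeric.isna() & df[col].notna()]
        if len(bad):
            raise ValueError(
                f"{path}, line {int(bad[0]) + 2}: non-numeric value "
                f"{df.loc[bad[0], col]!r} in feature column {col!r}"
            )
        if numeric.isna().any():
            row = int(df.index[numeric.isna()][0])
            raise ValueError(f"{path}, line {row + 2}: missing value in {col!r}")
        df[col] = numeric
    labels = pd.to_numeric(df["label"], errors="coerce")
    if labels.isna().any() or not np.allclose(labels, labels.round()):
        row = int(df.index[labels.isna() | (labels != labels.round())][0])
        raise ValueError(f"{path}, line {row + 2}: label must be an integer")
    t = labels.to_numpy().astype(int)
    if t.min() < 1:
        raise ValueError(f"{path}: labels must be 1-based positive integers")
    return df[feature_cols].to_numpy(dtype=float), t, feature_cols


def write_dataset(path, X: np.ndarray, t: np.ndarray, feature_names=None) -> None:
    X = np.asarray(X, dtype=float)
    names = (
        list(feature_names)
        if feature_names is not None
        else [f"f{i:03d}" for i in range(X.shape[1])]
    )
    df = pd.DataFrame(X, columns=names)
    df["label"] = np.asarray(t).ravel().astype(int)
    df.to_csv(path, index=False)


def _dump(obj: dict, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True) + "\n")


def save_projection(model: ProjectionModel, path) -> None:
    _dump(
        {
            "kind": "cka_projection",
            "shape": list(model.W.shape),
            "W": model.W.ravel().tolist(),
            "trace": [[int(i), float(r)] for i, r in model.trace],
            "relevance": model.relevance.tolist(),
            "relevance_raw": model.relevance_raw.tolist(),
            "config": asdict(model.config),
            "seed": model.seed,
            "feature_names": model.feature_names,
        },
        path,
    )


def load_projection(path) -> ProjectionModel:
    doc = json.loads(Path(path).read_text())
    m1, d = doc["shape"]
    return ProjectionModel(
        W=np.asarray(doc["W"], dtype=float).reshape(m1, d),
        trace=[(int(i), float(r)) for i, r in doc["trace"]],
        relevance=np.asarray(doc["relevance"], dtype=float),
        relevance_raw=np.asarray(doc["relevance_raw"], dtype=float),
        config=OptimizerConfig(**doc["config"]),
        seed=int(doc["seed"]),
        feature_names=doc["feature_names"],
    )


def save_network(params: NetworkParams, path, scaler=None, meta: dict | None = None) -> None:
    doc = {
        "kind": "network",
        "layers": [
            {"W": W.ravel().tolist(), "b": b.tolist(), "shape": list(W.shape)}
            for W, b in params.layers
        ],
        "meta": meta or {},
    }
    if scaler is not None:
        doc["scaler"] = {"mean": scaler.mean.tolist(), "std": scaler.std.tolist()}
    _dump(doc, path)


def load_network(path):
    from .preprocess import Scaler

    doc = json.loads(Path(path).read_text())
    layers = [
        (
            np.asarray(l["W"], dtype=float).reshape(l["shape"]),
            np.asarray(l["b"], dtype=float),
        )
        for l in doc["layers"]
    ]
    scaler = None
    if "scaler" in doc:
        scaler = Scaler(
            np.asarray(doc["scaler"]["mean"]), np.asarray(doc["scaler"]["std"])
        )
    return NetworkParams(layers), scaler, doc.get("meta", {})


def save_report(report: EvaluationReport, path) -> None:
    _dump({"kind": "evaluation", **report.to_dict()}, path)
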