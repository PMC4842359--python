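"""Multiclass evaluation, cross-validated model selection and the
initialization comparison experiment.

Metrics follow the standard multiclass vocabulary for a C-class softmax
classifier:

- accuracy ``alpha = trace(confusion) / N``;
- class-wise true positive rate (recall) ``tau^c = tp^c / N^c``;
- one-vs-rest AUC ``beta^c``: area under the ROC curve with class c as
  positive, scored by the class-c posterior, trapezoidal rule with tied
  scores grouped; ``beta`` is the class-size weighted mean of the
  ``beta^c``.

``alpha`` equals the N^c-weighted mean of the ``tau^c`` — an algebraic
identity of the trace form that the test suite asserts on random confusion
matrices.

Hidden-size selection runs stratified 5-fold cross-validation per candidate
width and picks the highest mean-to-deviation ratio of the fold accuracies
(mean / (std + 1e-8)): among similarly accurate widths, prefer the most
stable; ties go to the smallest width.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import TrainConfig, forward, init_network, train
from .preprocess import fit_scaler

__all__ = [
    "EvaluationReport",
    "TuningResult",
    "confusion",
    "roc_curve",
    "auc_trapezoid",
    "metrics",
    "kfold_split",
    "tune_hidden_size",
    "evaluate_classifier",
    "compare_inits",
    "STRATEGIES",
]

STRATEGIES = ("random", "aen", "pca", "cka")


@dataclass
class EvaluationReport:
    """Full multiclass evaluation of one fitted classifier."""

    confusion: np.ndarray
    alpha: float
    tau: np.ndarray  # per-class recall; NaN for classes absent from t_true
    beta: float
    beta_per_class: np.ndarray  # NaN for absent classes
    roc: list[tuple[np.ndarray, np.ndarray]]  # per-class (fpr, tpr)

    def to_dict(self) -> dict:
        return {
            "confusion": self.confusion.tolist(),
            "alpha": self.alpha,
            "tau": self.tau.tolist(),
            "beta": self.beta,
            "beta_per_class": self.beta_per_class.tolist(),
            "roc": [
                {"fpr": f.tolist(), "tpr": t.tolist()} for f, t in self.roc
            ],
        }


@dataclass
class TuningResult:
    grid: list[int]
    fold_accuracies: dict[int, list[float]]
    criterion: dict[int, float]
    selected_m1: int


def confusion(t_true: np.ndarray, t_pred: np.ndarray, n_classes: int | None = None) -> np.ndarray:
    """C x C count matrix, rows = true class, columns = predicted class."""
    t_true = np.asarray(t_true).ravel().astype(int)
    t_pred = np.asarray(t_pred).ravel().astype(int)
    if t_true.shape != t_pred.shape:
        raise ValueError(
            f"label vectors differ in length: {t_true.size} vs {t_pred.size}"
        )
    C = int(n_classes) if n_classes is not None else int(max(t_true.max(), t_pred.max()))
    if t_true.min() < 1 or t_pred.min() < 1 or max(t_true.max(), t_pred.max()) > C:
        raise ValueError(f"labels must lie in 1..{C}")
    M = np.zeros((C, C), dtype=int)
    np.add.at(M, (t_true - 1, t_pred - 1), 1)
    return M


def roc_curve(scores: np.ndarray, positive: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One-vs-rest ROC points, tied scores grouped into single thresholds.

    Returns (fpr, tpr) arrays starting at (0, 0) and ending at (1, 1), both
    monotone non-decreasing.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    positive = np.asarray(positive, dtype=bool).ravel()
    n_pos = int(positive.sum())
    n_neg = positive.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs at least one positive and one negative sample")
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    p = positive[order].astype(float)
    # group equal scores: keep only the last index of each tie block
    last_of_block = np.r_[np.flatnonzero(np.diff(s) != 0), s.size - 1]
    tp = np.cumsum(p)[last_of_block]
    fp = np.cumsum(1.0 - p)[last_of_block]
    tpr = np.r_[0.0, tp / n_pos]
    fpr = np.r_[0.0, fp / n_neg]
    return fpr, tpr


def auc_trapezoid(fpr: np.ndarray, tpr: np.ndarray) -> float:
    """Area under a ROC curve by the trapezoidal rule."""
    return float(np.trapezoid(tpr, fpr))


def metrics(
    conf: np.ndarray, scores: np.ndarray, t_true: np.ndarray
) -> EvaluationReport:
    """Compute alpha, per-class tau, one-vs-rest beta and ROC curves.

    ``scores`` holds the per-sample class posteriors (N x C) used for the
    AUCs; ``conf`` must be the confusion matrix of the argmax predictions on
    the same samples. Classes absent from ``t_true`` get NaN tau/beta and
    are excluded from the weighted beta with a warning.
    """
    conf = np.asarray(conf)
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    t_true = np.asarray(t_true).ravel().astype(int)
    C = conf.shape[0]
    if conf.shape != (C, C):
        raise ValueError("confusion matrix must be square")
    if scores.shape != (t_true.size, C):
        raise ValueError(
            f"scores shape {scores.shape} does not match N={t_true.size}, C={C}"
        )
    n_per_class = conf.sum(axis=1)
    if int(n_per_class.sum()) != t_true.size:
        raise ValueError("confusion matrix total disagrees with sample count")

    alpha = float(np.trace(conf) / conf.sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        tau = np.where(n_per_class > 0, np.diag(conf) / n_per_class, np.nan)

    beta_pc = np.full(C, np.nan)
    roc: list[tuple[np.ndarray, np.ndarray]] = []
    for c in range(C):
        pos = t_true == c + 1
        if pos.sum() == 0 or pos.sum() == pos.size:
            warnings.warn(
                f"class {c + 1} has no positives or no negatives; its tau/beta "
                "are undefined and excluded from the weighted beta"
            )
            roc.append((np.array([0.0, 1.0]), np.array([0.0, 1.0])))
            continue
        fpr, tpr = roc_curve(scores[:, c], pos)
        roc.append((fpr, tpr))
        beta_pc[c] = auc_trapezoid(fpr, tpr)
    ok = ~np.isnan(beta_pc)
    beta = float(np.sum(beta_pc[ok] * n_per_class[ok]) / np.sum(n_per_class[ok]))
    return EvaluationReport(
        confusion=conf, alpha=alpha, tau=tau, beta=beta, beta_per_class=beta_pc, roc=roc
    )


def kfold_split(
    N: int, k: int = 5, seed: int = 0, stratify_by: np.ndarray | None = None
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Seeded stratified k-fold: disjoint, exhaustive (train, validation) pairs.

    With stratification, each class's shuffled members are dealt round-robin
    across folds, so per-fold class proportions match the global ones to
    within one sample.
    """
    if k < 2 or k > N:
        raise ValueError(f"k must lie in 2..N, got k={k}, N={N}")
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    if stratify_by is None:
        groups = [np.arange(N)]
    else:
        t = np.asarray(stratify_by).ravel()
        if t.size != N:
            raise ValueError("stratify_by length must equal N")
        groups = [np.flatnonzero(t == c) for c in np.unique(t)]
        small = [g for g in groups if g.size < k]
        if small:
            warnings.warn(
                f"{len(small)} class(es) have fewer than k={k} members; "
                "stratification is degenerate for them"
            )
    offset = 0
    for g in groups:
        g = g.copy()
        rng.shuffle(g)
        for i, idx in enumerate(g):
            folds[(i + offset) % k].append(int(idx))
        offset += g.size  # rotate the start fold so fold sizes balance
    out = []
    for i in range(k):
        val = np.sort(np.asarray(folds[i], dtype=int))
        tr = np.sort(np.asarray([j for f in folds[:i] + folds[i + 1 :] for j in f], dtype=int))
        out.append((tr, val))
    return out


def _fit_and_score(
    X_tr: np.ndarray,
    t_tr: np.ndarray,
    X_val: np.ndarray,
    t_val: np.ndarray,
    strategy: str,
    m1: int,
    seed: int,
    train_cfg: TrainConfig,
    n_classes: int,
    strategy_kwargs: dict | None = None,
) -> tuple[float, "NetworkParamsLike", np.ndarray]:
    scaler = fit_scaler(X_tr)
    Xs_tr = scaler.transform(X_tr)
    Xs_val = scaler.transform(X_val)
    params = init_network(
        strategy, Xs_tr, t_tr, m1, seed=seed, n_classes=n_classes,
        **(strategy_kwargs or {}),
    )
    params, _ = train(params, Xs_tr, t_tr, train_cfg)
    _, probs = forward(params, Xs_val)
    pred = np.argmax(probs, axis=1) + 1
    acc = float(np.mean(pred == t_val))
    return acc, params, probs


def tune_hidden_size(
    X: np.ndarray,
    t: np.ndarray,
    strategy: str,
    grid: list[int],
    seed: int = 0,
    k: int = 5,
    train_cfg: TrainConfig | None = None,
    strategy_kwargs: dict | None = None,
) -> TuningResult:
    """Select the hidden width by the highest CV mean-to-deviation ratio."""
    grid = [int(m) for m in grid]
    if not grid:
        raise ValueError("hidden-size grid is empty")
    X = np.asarray(X, dtype=float)
    t = np.asarray(t).ravel().astype(int)
    if any(m > X.shape[1] for m in grid):
        raise ValueError("grid contains widths larger than the feature count")
    train_cfg = train_cfg if train_cfg is not None else TrainConfig(seed=seed)
    C = int(t.max())
    splits = kfold_split(X.shape[0], k=k, seed=seed, stratify_by=t)
    fold_acc: dict[int, list[float]] = {}
    criterion: dict[int, float] = {}
    for m1 in grid:
        accs = []
        for tr, val in splits:
            acc, _, _ = _fit_and_score(
                X[tr], t[tr], X[val], t[val], strategy, m1, seed, train_cfg, C,
                strategy_kwargs,
            )
            accs.append(acc)
        fold_acc[m1] = accs
        criterion[m1] = float(np.mean(accs) / (np.std(accs) + 1e-8))
    best = None
    for m1 in sorted(grid):  # ties resolve to the smallest width
        if best is None or criterion[m1] > criterion[best]:
            best = m1
    return TuningResult(
        grid=grid, fold_accuracies=fold_acc, criterion=criterion, selected_m1=best
    )


def evaluate_classifier(params, X: np.ndarray, t: np.ndarray) -> EvaluationReport:
    """Evaluate a trained network on (already standardized) data."""
    t = np.asarray(t).ravel().astype(int)
    _, probs = forward(params, X)
    pred = np.argmax(probs, axis=1) + 1
    conf = confusion(t, pred, n_classes=probs.shape[1])
    return metrics(conf, probs, t)


def compare_inits(
    X_train: np.ndarray,
    t_train: np.ndarray,
    X_test: np.ndarray,
    t_test: np.ndarray,
    seeds: list[int],
    strategies: tuple[str, ...] = STRATEGIES,
    m1: int | list[int] = 14,
    train_cfg: TrainConfig | None = None,
    class_names: list[str] | None = None,
) -> tuple[dict[str, list[EvaluationReport]], pd.DataFrame]:
    """Train and evaluate each initialization strategy across seeds.

    ``m1`` may be a single width (no tuning) or a grid, in which case the
    width is tuned once per strategy on the training split with the first
    seed, then reused for every seed. Returns the per-strategy reports and a
    summary table with mean +/- sd of alpha, per-class tau, beta and
    per-class beta over seeds (fractions in [0, 1]).

    Unless a ``train_cfg`` overrides it, training uses patience-20 early
    stopping on a held-out tenth of the training split: the comparison is
    meant to measure what each initialization lets the net generalize to,
    and without a stopping rule every strategy drifts into overfitting.
    """
    X_train = np.asarray(X_train, dtype=float)
    X_test = np.asarray(X_test, dtype=float)
    t_train = np.asarray(t_train).ravel().astype(int)
    t_test = np.asarray(t_test).ravel().astype(int)
    C = int(max(t_train.max(), t_test.max()))
    if class_names is None:
        class_names = ["NC", "MCI", "AD"] if C == 3 else [str(c + 1) for c in range(C)]
    base_cfg = train_cfg if train_cfg is not None else TrainConfig(early_stop_patience=20)

    reports: dict[str, list[EvaluationReport]] = {}
    rows = []
    for strategy in strategies:
        if isinstance(m1, (list, tuple, np.ndarray)):
            tuned = tune_hidden_size(
                X_train, t_train, strategy, list(m1), seed=int(seeds[0]),
                train_cfg=base_cfg,
            )
            width = tuned.selected_m1
        else:
            width = int(m1)
        strat_reports = []
        for seed in seeds:
            cfg = TrainConfig(
                epochs=base_cfg.epochs,
                batch_size=base_cfg.batch_size,
                learning_rate=base_cfg.learning_rate,
                seed=int(seed),
                early_stop_patience=base_cfg.early_stop_patience,
                holdout_fraction=base_cfg.holdout_fraction,
            )
            scaler = fit_scaler(X_train)
            Xs_tr = scaler.transform(X_train)
            Xs_te = scaler.transform(X_test)
            params = init_network(
                strategy, Xs_tr, t_train, width, seed=int(seed), n_classes=C
            )
            params, _ = train(params, Xs_tr, t_train, cfg)
            strat_reports.append(evaluate_classifier(params, Xs_te, t_test))
        reports[strategy] = strat_reports

        row: dict[str, object] = {"strategy": strategy, "m1": width}
        stats = {
            "alpha": [r.alpha for r in strat_reports],
            "beta": [r.beta for r in strat_reports],
        }
        for c, name in enumerate(class_names):
            stats[f"tau_{name}"] = [r.tau[c] for r in strat_reports]
            stats[f"beta_{name}"] = [r.beta_per_class[c] for r in strat_reports]
        order = ["alpha"] + [f"tau_{n}" for n in class_names] + ["beta"] + [
            f"beta_{n}" for n in class_names
        ]
        for key in order:
            vals = np.asarray(stats[key], dtype=float)
            row[f"{key}_mean"] = float(np.nanmean(vals))
            row[f"{key}_sd"] = float(np.nanstd(vals))
        rows.append(row)
    return reports, pd.DataFrame(rows)
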