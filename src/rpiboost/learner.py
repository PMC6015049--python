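"""Gradient-boosted-tree classifier, nested cross-validation, and metrics.

The classifier is an XGBoost binary-logistic ensemble with the published
configuration: 200 trees, learning rate 0.25, maximum depth 8, L1 penalty
1.12, L2 penalty 18.51, subsample ratio 0.9. Generalization is estimated by
stratified 10-fold nested cross-validation: the outer folds score the model,
an inner grid search over the regularization penalties picks the
configuration per outer training set.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import xgboost as xgb
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

logger = logging.getLogger(__name__)

#: Inner-search grid over (L1, L2) penalties; includes the published values.
DEFAULT_PENALTY_GRID: tuple[tuple[float, float], ...] = tuple(
    (l1, l2) for l1 in (0.0, 0.5, 1.12, 2.0) for l2 in (1.0, 10.0, 18.51, 30.0)
)

#: Small grid for desk-scale runs (published configuration vs. near-unregularized).
SMALL_PENALTY_GRID: tuple[tuple[float, float], ...] = ((1.12, 18.51), (0.0, 1.0))


@dataclass(frozen=True)
class ModelConfig:
    n_trees: int = 200
    learning_rate: float = 0.25
    max_depth: int = 8
    l1_penalty: float = 1.12
    l2_penalty: float = 18.51
    subsample_ratio: float = 0.9
    loss: str = "binary:logistic"
    decision_threshold: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.decision_threshold < 1:
            raise ValueError("decision_threshold must be in (0, 1)")
        for name in ("n_trees", "learning_rate", "max_depth", "subsample_ratio"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class ConfusionCounts:
    TP: int = 0
    TN: int = 0
    FP: int = 0
    FN: int = 0

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass
class EvalReport:
    fold_metrics: list[dict] = field(default_factory=list)
    fold_counts: list[ConfusionCounts] = field(default_factory=list)
    mean: dict = field(default_factory=dict)
    sd: dict = field(default_factory=dict)
    config: ModelConfig | None = None
    chosen_penalties: list[tuple[float, float]] = field(default_factory=list)

    def to_tsv(self) -> str:
        names = ["accuracy", "precision", "recall", "f_score", "auroc"]
        lines = ["fold\t" + "\t".join(names) + "\tTP\tTN\tFP\tFN"]
        for i, (m, c) in enumerate(zip(self.fold_metrics, self.fold_counts), 1):
            vals = "\t".join(f"{m[n]:.4f}" for n in names)
            lines.append(f"{i}\t{vals}\t{c.TP}\t{c.TN}\t{c.FP}\t{c.FN}")
        lines.append(
            "mean\t" + "\t".join(f"{self.mean[n]:.4f}" for n in names) + "\t-\t-\t-\t-"
        )
        lines.append(
            "sd\t" + "\t".join(f"{self.sd[n]:.4f}" for n in names) + "\t-\t-\t-\t-"
        )
        return "\n".join(lines) + "\n"


def _make_classifier(config: ModelConfig) -> xgb.XGBClassifier:
    return xgb.XGBClassifier(
        n_estimators=config.n_trees,
        learning_rate=config.learning_rate,
        max_depth=config.max_depth,
        reg_alpha=config.l1_penalty,
        reg_lambda=config.l2_penalty,
        subsample=config.subsample_ratio,
        objective=config.loss,
        tree_method="hist",
        n_jobs=1,
        random_state=config.seed,
    )


def train(
    features: np.ndarray, labels: np.ndarray, config: ModelConfig | None = None
) -> xgb.XGBClassifier:
    """Fit the boosted-tree ensemble with the given configuration."""
    config = config or ModelConfig()
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    if X.shape[0] < 10:
        raise ValueError(f"need at least 10 rows to train, got {X.shape[0]}")
    if np.isnan(X).any():
        raise ValueError("features contain NaN")
    if len(np.unique(y)) < 2:
        raise ValueError("labels contain a single class; need both 0 and 1")
    model = _make_classifier(config)
    model.fit(X, y)
    return model


def save_model(model: xgb.XGBClassifier, path: str | Path) -> None:
    """Write the model as XGBoost's portable JSON dump.

    The dump is written from the underlying booster; the sklearn wrapper
    restores itself from it on load.
    """
    model.get_booster().save_model(str(path))


def load_model(path: str | Path) -> xgb.XGBClassifier:
    model = xgb.XGBClassifier()
    model.load_model(str(path))
    return model


def predict(
    model: xgb.XGBClassifier,
    vectors: np.ndarray,
    threshold: float = 0.5,
) -> list[tuple[float, bool]]:
    """Per-pair interaction probability and binary call (call = prob >= threshold)."""
    X = np.atleast_2d(np.asarray(vectors, dtype=float))
    expected = model.n_features_in_
    if X.shape[1] != expected:
        raise ValueError(
            f"feature dimension mismatch: model expects {expected}, got {X.shape[1]}"
        )
    probs = model.predict_proba(X)[:, 1]
    return [(float(p), bool(p >= threshold)) for p in probs]


def compute_metrics(
    counts: ConfusionCounts,
    scores: np.ndarray | None = None,
    labels: np.ndarray | None = None,
) -> dict:
    """Accuracy, precision, recall, F-score from confusion counts; AUROC from
    the ranked scores (trapezoidal) when scores and labels are given.

    Precision with TP+FP = 0 (and recall with TP+FN = 0) is reported as 0
    with a warning rather than raising.
    """
    tp, tn, fp, fn = counts.TP, counts.TN, counts.FP, counts.FN
    total = tp + tn + fp + fn
    if total == 0:
        raise ValueError("empty confusion counts")
    accuracy = (tp + tn) / total
    if tp + fp == 0:
        warnings.warn("no positive calls; precision undefined, reporting 0", stacklevel=2)
        precision = 0.0
    else:
        precision = tp / (tp + fp)
    if tp + fn == 0:
        warnings.warn("no positive labels; recall undefined, reporting 0", stacklevel=2)
        recall = 0.0
    else:
        recall = tp / (tp + fn)
    if precision + recall == 0:
        f_score = 0.0
    else:
        f_score = 2 * (precision * recall) / (precision + recall)
    out = {
        "accuracy": accuracy,
        "precision": precision,
        "recall": recall,
        "f_score": f_score,
    }
    if scores is not None and labels is not None:
        labels = np.asarray(labels, dtype=int)
        if len(np.unique(labels)) == 2:
            out["auroc"] = float(roc_auc_score(labels, np.asarray(scores, dtype=float)))
        else:
            out["auroc"] = float("nan")
    return out


def counts_from_predictions(
    labels: np.ndarray, calls: np.ndarray
) -> ConfusionCounts:
    labels = np.asarray(labels, dtype=bool)
    calls = np.asarray(calls, dtype=bool)
    return ConfusionCounts(
        TP=int(np.sum(calls & labels)),
        TN=int(np.sum(~calls & ~labels)),
        FP=int(np.sum(calls & ~labels)),
        FN=int(np.sum(~calls & labels)),
    )


def nested_cv(
    features: np.ndarray,
    labels: np.ndarray,
    config: ModelConfig | None = None,
    outer_folds: int = 10,
    inner_folds: int = 5,
    grid: tuple[tuple[float, float], ...] = DEFAULT_PENALTY_GRID,
    seed: int = 0,
) -> EvalReport:
    """Stratified nested cross-validation.

    Outer folds estimate generalization; for each outer training set an inner
    stratified grid search over (L1, L2) penalties selects the configuration
    with the best mean inner accuracy, which is then refit on the full outer
    training set and scored on the outer test fold.
    """
    config = config or ModelConfig(seed=seed)
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    class_counts = np.bincount(y, minlength=2)
    if class_counts.min() < outer_folds:
        raise ValueError(
            f"need at least {outer_folds} examples per class for {outer_folds} "
            f"outer folds (have {class_counts.tolist()}); use fewer folds"
        )
    outer = StratifiedKFold(n_splits=outer_folds, shuffle=True, random_state=seed)
    report = EvalReport(config=config)
    for fold_i, (tr, te) in enumerate(outer.split(X, y)):
        Xtr, ytr, Xte, yte = X[tr], y[tr], X[te], y[te]
        best_pen, best_acc = grid[0], -1.0
        if len(grid) > 1:
            inner = StratifiedKFold(
                n_splits=inner_folds, shuffle=True, random_state=seed + 1
            )
            inner_splits = list(inner.split(Xtr, ytr))
            for l1, l2 in grid:
                cfg = replace(config, l1_penalty=l1, l2_penalty=l2)
                accs = []
                for itr, ite in inner_splits:
                    m = _make_classifier(cfg)
                    m.fit(Xtr[itr], ytr[itr])
                    accs.append(float(np.mean(m.predict(Xtr[ite]) == ytr[ite])))
                mean_acc = float(np.mean(accs))
                if mean_acc > best_acc:
                    best_acc, best_pen = mean_acc, (l1, l2)
        cfg = replace(config, l1_penalty=best_pen[0], l2_penalty=best_pen[1])
        model = _make_classifier(cfg)
        model.fit(Xtr, ytr)
        probs = model.predict_proba(Xte)[:, 1]
        calls = probs >= config.decision_threshold
        counts = counts_from_predictions(yte, calls)
        metrics = compute_metrics(counts, probs, yte)
        report.fold_counts.append(counts)
        report.fold_metrics.append(metrics)
        report.chosen_penalties.append(best_pen)
        logger.info("outer fold %d: %s (penalties %s)", fold_i + 1, metrics, best_pen)
    names = report.fold_metrics[0].keys()
    report.mean = {
        n: float(np.mean([m[n] for m in report.fold_metrics])) for n in names
    }
    report.sd = {
        n: float(np.std([m[n] for m in report.fold_metrics], ddof=1)) for n in names
    }
    return report
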