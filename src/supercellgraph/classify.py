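"""Repeated stratified cross-validated multi-class classification of image
feature vectors, reported as mean +/- std over repeats.

The default classifier is an L2-regularized multinomial logistic regression
inside a pipeline that standardizes features on the training folds only, so
no statistic of a held-out sample ever reaches the fit. Accuracy is computed
over the pooled held-out predictions of each repeat; one-vs-rest AUC per
class comes from the pooled held-out class scores of each repeat. The std
reported is the sample standard deviation (ddof=1) across repeats.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import confusion_matrix, roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .errors import DataSizeError, ValidationError


@dataclass
class ClassificationResult:
    accuracy_mean: float
    accuracy_std: float
    auc_mean: np.ndarray           # (n_classes,) one-vs-rest
    auc_std: np.ndarray            # (n_classes,)
    accuracy_per_repeat: np.ndarray  # (repeats,)
    auc_per_repeat: np.ndarray     # (repeats, n_classes)
    predictions_per_repeat: np.ndarray  # (repeats, n_samples) held-out predictions
    confusion: np.ndarray          # (n_classes, n_classes) summed over repeats
    classes: np.ndarray
    config: dict = field(default_factory=dict)  # folds, repeats, seed, classifier

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ClassificationResult):
            return NotImplemented
        return (
            self.accuracy_mean == other.accuracy_mean
            and self.accuracy_std == other.accuracy_std
            and np.array_equal(self.auc_per_repeat, other.auc_per_repeat)
            and np.array_equal(self.accuracy_per_repeat, other.accuracy_per_repeat)
            and np.array_equal(self.predictions_per_repeat, other.predictions_per_repeat)
            and np.array_equal(self.confusion, other.confusion)
            and np.array_equal(self.classes, other.classes)
            and self.config == other.config
        )

    def to_dict(self) -> dict:
        return {
            "accuracy_mean": float(self.accuracy_mean),
            "accuracy_std": float(self.accuracy_std),
            "auc_mean": [float(v) for v in self.auc_mean],
            "auc_std": [float(v) for v in self.auc_std],
            "confusion": self.confusion.tolist(),
            "classes": self.classes.tolist(),
            "config": self.config,
        }

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    def render_table(self, method: str = "supercell-graph", class_names: list[str] | None = None) -> str:
        """Plain-text results table: Method / Accuracy / per-class AUC, mean +/- std."""
        if class_names is None:
            class_names = [f"class {c}" for c in self.classes]
        header = ["Method", "Accuracy"] + [f"AUC ({name})" for name in class_names]
        row = [method, f"{self.accuracy_mean:.3f} ± {self.accuracy_std:.3f}"] + [
            f"{m:.3f} ± {s:.3f}" for m, s in zip(self.auc_mean, self.auc_std)
        ]
        widths = [max(len(h), len(r)) for h, r in zip(header, row)]
        fmt = "  ".join(f"{{:<{w}}}" for w in widths)
        return fmt.format(*header) + "\n" + fmt.format(*row)


def _default_classifier(seed: int) -> Pipeline:
    return Pipeline([
        ("scale", StandardScaler()),
        ("clf", LogisticRegression(C=1.0, max_iter=2000, random_state=seed)),
    ])


def cross_validate(
    features: np.ndarray,
    labels: np.ndarray,
    folds: int = 5,
    repeats: int = 20,
    seed: int = 0,
    classifier=None,
) -> ClassificationResult:
    """Repeats x stratified-folds CV with within-fold standardization."""
    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValidationError("need at least 2 classes")
    for cls, cnt in zip(classes, counts):
        if cnt < folds:
            raise DataSizeError(
                f"class {cls!r} has only {cnt} samples, fewer than {folds} folds"
            )
    class_index = {c: i for i, c in enumerate(classes)}
    y_idx = np.asarray([class_index[v] for v in y])
    n_classes = len(classes)
    n = len(y)

    acc = np.empty(repeats)
    auc = np.empty((repeats, n_classes))
    preds = np.empty((repeats, n), dtype=np.int64)
    conf = np.zeros((n_classes, n_classes), dtype=np.int64)
    for r in range(repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed + r)
        scores = np.empty((n, n_classes))
        pred = np.empty(n, dtype=np.int64)
        for train, test in skf.split(X, y_idx):
            model = classifier if classifier is not None else _default_classifier(seed)
            from sklearn.base import clone

            model = clone(model)
            model.fit(X[train], y_idx[train])
            proba = model.predict_proba(X[test])
            # align column order with `classes` (sklearn sorts its classes_)
            for col, c in enumerate(model.classes_):
                scores[test, c] = proba[:, col]
            pred[test] = model.classes_[proba.argmax(axis=1)]
        acc[r] = float((pred == y_idx).mean())
        for c in range(n_classes):
            auc[r, c] = roc_auc_score((y_idx == c).astype(int), scores[:, c])
        preds[r] = pred
        conf += confusion_matrix(y_idx, pred, labels=np.arange(n_classes))
    ddof = 1 if repeats > 1 else 0
    return ClassificationResult(
        accuracy_mean=float(acc.mean()),
        accuracy_std=float(acc.std(ddof=ddof)),
        auc_mean=auc.mean(axis=0),
        auc_std=auc.std(axis=0, ddof=ddof),
        accuracy_per_repeat=acc,
        auc_per_repeat=auc,
        predictions_per_repeat=preds,
        confusion=conf,
        classes=classes,
        config={
            "folds": int(folds),
            "repeats": int(repeats),
            "seed": int(seed),
            "classifier": "logistic-regression-l2" if classifier is None else type(classifier).__name__,
        },
    )
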