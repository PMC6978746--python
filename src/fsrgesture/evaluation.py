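"""Cross-validation, confusion matrices, ablation and reproducibility tests.

The headline accuracy of k-fold cross-validation is the mean of the k
per-fold accuracies (the pooled over-all-held-out-predictions accuracy is
also reported); leave-one-out is n-fold with singleton folds and is
deterministic given the database.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .classifiers import TrainedModel
from .features import SENSOR_MASKS, GestureDatabase, project_sensors
from .labels import GestureLabel

Trainer = Callable[[GestureDatabase], TrainedModel]


@dataclass
class EvalResult:
    """Evaluation outcome: accuracies in percent and the confusion matrix
    (rows = true gestures, columns = predicted gestures)."""

    accuracy: float
    pooled_accuracy: float
    per_class_accuracy: dict[int, float]
    confusion: pd.DataFrame
    fold_accuracies: np.ndarray

    @property
    def n_instances(self) -> int:
        return int(self.confusion.to_numpy().sum())


def _confusion_frame(classes: np.ndarray) -> pd.DataFrame:
    names = [GestureLabel(c).name.lower() for c in classes]
    return pd.DataFrame(
        np.zeros((len(classes), len(classes)), dtype=int), index=names, columns=names
    )


def _result_from_confusion(
    confusion: pd.DataFrame, fold_accuracies: Sequence[float]
) -> EvalResult:
    mat = confusion.to_numpy()
    total = mat.sum()
    pooled = 100.0 * np.trace(mat) / total if total else 0.0
    row_sums = mat.sum(axis=1)
    per_class = {
        int(GestureLabel.from_name(name)): (
            100.0 * mat[i, i] / row_sums[i] if row_sums[i] else np.nan
        )
        for i, name in enumerate(confusion.index)
    }
    fold_accuracies = np.asarray(fold_accuracies, dtype=float)
    return EvalResult(
        accuracy=100.0 * float(fold_accuracies.mean()),
        pooled_accuracy=float(pooled),
        per_class_accuracy=per_class,
        confusion=confusion,
        fold_accuracies=fold_accuracies,
    )


def evaluate(model: TrainedModel, db: GestureDatabase) -> EvalResult:
    """Straight held-out evaluation of a trained model on a database."""
    classes = np.unique(np.concatenate([model.classes, db.classes]))
    confusion = _confusion_frame(classes)
    preds = model.predict_db(db)
    for true, pred in zip(db.y, preds):
        confusion.iloc[
            int(np.searchsorted(classes, true)), int(np.searchsorted(classes, pred))
        ] += 1
    acc = float(np.mean(preds == db.y))
    return _result_from_confusion(confusion, [acc])


def stratified_fold_indices(
    y: np.ndarray, k: int, seed: int = 42
) -> list[np.ndarray]:
    """Stratified k-fold assignment: shuffle each class and deal its rows
    round-robin over the folds.  Falls back to unstratified folding (with a
    warning) when some class has fewer than k rows."""
    y = np.asarray(y)
    n = len(y)
    if k > n:
        raise ValueError(f"k={k} exceeds the {n} available rows")
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    counts = np.bincount(y)
    if (counts[counts > 0] < k).any():
        warnings.warn(
            "some class has fewer rows than folds; using unstratified folds",
            stacklevel=2,
        )
        order = rng.permutation(n)
        for pos, idx in enumerate(order):
            folds[pos % k].append(int(idx))
    else:
        start = 0
        for c in np.unique(y):
            idx = rng.permutation(np.flatnonzero(y == c))
            for pos, row in enumerate(idx):
                folds[(start + pos) % k].append(int(row))
            start += len(idx)  # rotate so fold sizes stay balanced
    return [np.sort(np.array(f, dtype=int)) for f in folds]


def cross_validate(
    db: GestureDatabase,
    trainer: Trainer,
    scheme: str = "kfold",
    k: int = 10,
    seed: int = 42,
) -> EvalResult:
    """k-fold (stratified, seeded) or leave-one-out cross-validation.

    The headline ``accuracy`` is the mean of per-fold accuracies; the
    confusion matrix accumulates every held-out prediction.
    """
    if scheme == "kfold":
        folds = stratified_fold_indices(db.y, k, seed)
    elif scheme == "loo":
        folds = [np.array([i]) for i in range(db.n_rows)]
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    classes = db.classes
    confusion = _confusion_frame(classes)
    fold_accs = []
    all_idx = np.arange(db.n_rows)
    for fold in folds:
        train_idx = np.setdiff1d(all_idx, fold)
        model = trainer(db.subset(train_idx))
        test = db.subset(fold)
        preds = model.predict_db(test)
        for true, pred in zip(test.y, preds):
            confusion.iloc[
                int(np.searchsorted(classes, true)),
                int(np.searchsorted(classes, pred)),
            ] += 1
        fold_accs.append(float(np.mean(preds == test.y)))
    return _result_from_confusion(confusion, fold_accs)


def ablation_study(
    dbs: Sequence[GestureDatabase],
    trainers: Mapping[str, Trainer],
    k: int = 10,
    seed: int = 42,
    masks: Sequence[tuple[int, ...]] = SENSOR_MASKS,
) -> pd.DataFrame:
    """10-fold CV accuracy for every sensor subset, classifier and subject.

    Returns a long-format frame with columns ``sensors`` (e.g. "1+3"),
    ``classifier``, ``subject_id`` and ``accuracy`` (percent); aggregate
    with :func:`summarize_ablation`.
    """
    rows = []
    for mask in masks:
        for db in dbs:
            projected = project_sensors(db, mask)
            for name, trainer in trainers.items():
                res = cross_validate(projected, trainer, "kfold", k=k, seed=seed)
                rows.append(
                    {
                        "sensors": "+".join(str(i) for i in mask),
                        "n_sensors": len(mask),
                        "classifier": name,
                        "subject_id": db.subject_id,
                        "accuracy": res.accuracy,
                    }
                )
    return pd.DataFrame(rows)


def summarize_ablation(table: pd.DataFrame) -> pd.DataFrame:
    """Mean and SD of accuracy across subjects per sensor subset/classifier."""
    return (
        table.groupby(["sensors", "n_sensors", "classifier"], as_index=False)
        .agg(mean_accuracy=("accuracy", "mean"), sd_accuracy=("accuracy", "std"))
        .sort_values(["n_sensors", "sensors", "classifier"])
        .reset_index(drop=True)
    )


def reproducibility_eval(
    model: TrainedModel, second_session: GestureDatabase
) -> EvalResult:
    """Classify a later session with a model trained on an earlier one
    (no retraining) — the armband re-donning scenario."""
    return evaluate(model, second_session)
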