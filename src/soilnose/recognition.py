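"""Hierarchical (distributed) recognition model with grid-searched stages.

The cascade has three functional modules: a stage-1 soil-condition
classifier (healthy / petroleum / pesticide) over all records, and two
stage-2 specific classifiers — gasoline vs diesel on the petroleum branch,
six pesticide types on the pesticide branch — each trained only on records
whose true condition matches the branch.  At prediction time a record first
receives a condition; healthy ends the cascade, otherwise the record is
routed to the matching stage-2 module, so the final label is always
consistent with the stage-1 decision.

Stages are SVMs (RBF kernel, z-scored features) or random forests (raw
features), with hyperparameters chosen by grid search under inner
stratified cross-validation on the training data only.  Performance is
estimated by stratified 10-fold cross-validation; the mean of the ten test
accuracies is the reported accuracy.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .dataset_io import (
    HEALTHY,
    PESTICIDE_CLASSES,
    PETROLEUM_CLASSES,
    LabeledDataset,
)
from .features import FeatureSpec, feature_matrix, featurize_dataset, featurize_record
from .synthetic_data import DEFAULT_SEED

MODEL_FORMAT_VERSION = "soilnose-cascade-1"

TASKS = ("condition", "petroleum", "pesticide", "end_to_end")

#: Default hyperparameter grids.  Listed order is the tie-break order.
DEFAULT_SVM_GRID: dict[str, list] = {
    "C": [0.1, 1.0, 10.0, 100.0, 1000.0],
    "gamma": [1e-4, 1e-3, 1e-2, 1e-1, 1.0],
}
DEFAULT_RF_GRID: dict[str, list] = {
    "n_estimators": [100, 300],
    "max_depth": [None, 10],
}


@dataclass
class ClassifierSpec:
    """Classifier family plus its grid-search space and inner-CV settings."""

    kind: str
    grid: dict[str, list] = field(default_factory=dict)
    inner_cv_folds: int = 3
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if self.kind not in ("SVM", "RF"):
            raise ValueError(f"kind must be 'SVM' or 'RF', got {self.kind!r}")
        if not self.grid:
            self.grid = dict(DEFAULT_SVM_GRID if self.kind == "SVM" else DEFAULT_RF_GRID)
        for name, values in self.grid.items():
            if not values:
                raise ValueError(f"empty candidate list for hyperparameter {name!r}")
        if self.inner_cv_folds < 2:
            raise ValueError(f"inner_cv_folds must be >= 2, got {self.inner_cv_folds}")


def default_classifier_specs(seed: int = DEFAULT_SEED) -> list[ClassifierSpec]:
    return [ClassifierSpec("SVM", seed=seed), ClassifierSpec("RF", seed=seed)]


def _make_estimator(spec: ClassifierSpec, params: Mapping[str, object]):
    if spec.kind == "SVM":
        return Pipeline(
            [
                ("scale", StandardScaler()),
                ("clf", SVC(kernel="rbf", **params)),
            ]
        )
    return RandomForestClassifier(random_state=spec.seed, n_jobs=1, **params)


@dataclass
class FittedStage:
    """One grid-search winner refitted on all of its training data."""

    estimator: object
    params: dict
    inner_cv_accuracy: float
    classes: np.ndarray

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.estimator.predict(X)


def _grid_points(grid: Mapping[str, list]):
    """Cartesian product preserving the listed order of keys and values."""
    names = list(grid)
    for combo in itertools.product(*(grid[n] for n in names)):
        yield dict(zip(names, combo))


def fit_stage(X: np.ndarray, y: Sequence[str], spec: ClassifierSpec) -> FittedStage:
    """Grid-search one stage under inner stratified CV, refit the winner.

    The winner maximises mean inner-CV accuracy; ties go to the
    first-listed grid point.  Deterministic given ``spec.seed``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError(
            f"degenerate task: need >= 2 classes, got {list(classes)}"
        )
    if counts.min() < spec.inner_cv_folds:
        small = classes[counts.argmin()]
        raise ValueError(
            f"class {small!r} has {counts.min()} members, fewer than "
            f"inner_cv_folds={spec.inner_cv_folds}"
        )
    inner = StratifiedKFold(
        n_splits=spec.inner_cv_folds, shuffle=True, random_state=spec.seed
    )
    splits = list(inner.split(X, y))
    best_params = None
    best_acc = -np.inf
    for params in _grid_points(spec.grid):
        correct = 0
        for train_idx, test_idx in splits:
            est = _make_estimator(spec, params)
            est.fit(X[train_idx], y[train_idx])
            correct += int((est.predict(X[test_idx]) == y[test_idx]).sum())
        acc = correct / len(y)
        if acc > best_acc:  # strict: first-listed wins ties
            best_acc = acc
            best_params = params
    final = _make_estimator(spec, best_params)
    final.fit(X, y)
    return FittedStage(final, dict(best_params), float(best_acc), classes)


# ---------------------------------------------------------------------------
# Cascade
# ---------------------------------------------------------------------------


@dataclass
class CascadeModel:
    """Fitted three-module recognition model with routing metadata."""

    feature_spec: FeatureSpec
    stage1: FittedStage
    stage2_petroleum: FittedStage
    stage2_pesticide: FittedStage
    chosen_hyperparams: dict
    seed: int
    scaler: dict | None = None  # stage-1 z-score parameters (SVM only)


@dataclass
class PredictionTrace:
    """Final label plus the per-stage decisions that produced it."""

    final_label: str
    condition: str
    stage2: str  # subtype label, or "skipped" on the healthy branch


def _stage1_scaler_params(stage: FittedStage) -> dict | None:
    est = stage.estimator
    if isinstance(est, Pipeline) and "scale" in est.named_steps:
        scaler = est.named_steps["scale"]
        return {"mean": scaler.mean_.copy(), "scale": scaler.scale_.copy()}
    return None


def _train_cascade_from_features(
    table: pd.DataFrame, feature_spec: FeatureSpec, classifier_spec: ClassifierSpec
) -> CascadeModel:
    X = feature_matrix(table)
    condition = table["condition"].to_numpy()
    class_id = table["class_id"].to_numpy()
    for cond, required in (
        ("healthy", (HEALTHY,)),
        ("petroleum", PETROLEUM_CLASSES),
        ("pesticide", PESTICIDE_CLASSES),
    ):
        present = set(class_id[condition == cond])
        missing = [c for c in required if c not in present]
        if missing:
            raise ValueError(
                f"training set missing class(es) {missing} on the {cond} branch"
            )
    stage1 = fit_stage(X, condition, classifier_spec)
    petro = condition == "petroleum"
    pest = condition == "pesticide"
    stage2_petroleum = fit_stage(X[petro], class_id[petro], classifier_spec)
    stage2_pesticide = fit_stage(X[pest], class_id[pest], classifier_spec)
    model = CascadeModel(
        feature_spec=feature_spec,
        stage1=stage1,
        stage2_petroleum=stage2_petroleum,
        stage2_pesticide=stage2_pesticide,
        chosen_hyperparams={
            "stage1": stage1.params,
            "stage2_petroleum": stage2_petroleum.params,
            "stage2_pesticide": stage2_pesticide.params,
        },
        seed=classifier_spec.seed,
        scaler=_stage1_scaler_params(stage1),
    )
    return model


def train_cascade(
    train_records: LabeledDataset,
    feature_spec: FeatureSpec,
    classifier_spec: ClassifierSpec,
) -> CascadeModel:
    """Featurize the training records and fit all three stages.

    Stage-2 classifiers see only the records whose *true* condition matches
    their branch; the stage-1 feature scaler is fitted on training data
    only (inside the SVM pipeline).
    """
    table = featurize_dataset(train_records, feature_spec)
    return _train_cascade_from_features(table, feature_spec, classifier_spec)


def _predict_rows(model: CascadeModel, X: np.ndarray) -> list[PredictionTrace]:
    conditions = model.stage1.predict(X)
    traces: list[PredictionTrace] = [None] * len(X)  # type: ignore[list-item]
    for cond, stage in (
        ("petroleum", model.stage2_petroleum),
        ("pesticide", model.stage2_pesticide),
    ):
        idx = np.flatnonzero(conditions == cond)
        if len(idx):
            labels = stage.predict(X[idx])
            for i, lab in zip(idx, labels):
                traces[i] = PredictionTrace(str(lab), cond, str(lab))
    for i, cond in enumerate(conditions):
        if cond == "healthy":
            traces[i] = PredictionTrace(HEALTHY, "healthy", "skipped")
    return traces


def predict_cascade(model: CascadeModel, record) -> PredictionTrace:
    """Run one record through the cascade; healthy ends the detection.

    The trace records the stage-1 condition and the stage-2 subtype (or
    ``"skipped"`` when stage 1 says healthy), so the final label can never
    contradict the routing decision.
    """
    fv = featurize_record(record, model.feature_spec)
    expected = model.stage1.estimator.n_features_in_ if hasattr(
        model.stage1.estimator, "n_features_in_"
    ) else len(fv.values)
    if len(fv.values) != expected:
        raise ValueError(
            f"feature shape mismatch: record yields {len(fv.values)} features, "
            f"model expects {expected}"
        )
    return _predict_rows(model, fv.values[None, :])[0]


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------


@dataclass
class FoldAssignment:
    """Stratified assignment of record_ids to the 10 CV folds."""

    assignment: dict[str, int]
    n_folds: int
    seed: int

    def fold_of(self, record_ids: Sequence[str]) -> np.ndarray:
        return np.array([self.assignment[r] for r in record_ids])

    def validate(self, labels_by_id: Mapping[str, str]) -> None:
        """Assert disjointness/coverage (by construction) and stratification."""
        folds = np.array(list(self.assignment.values()))
        if set(np.unique(folds)) != set(range(self.n_folds)):
            raise AssertionError("folds do not cover 0..n_folds-1")
        labels = np.array([labels_by_id[r] for r in self.assignment])
        for cls in np.unique(labels):
            per_fold = np.bincount(folds[labels == cls], minlength=self.n_folds)
            if per_fold.max() - per_fold.min() > 1:
                raise AssertionError(
                    f"stratification broken for class {cls!r}: fold counts {per_fold}"
                )


def make_folds(
    record_ids: Sequence[str],
    labels: Sequence[str],
    n_folds: int = 10,
    seed: int = DEFAULT_SEED,
) -> FoldAssignment:
    """Stratified fold assignment; per-class fold sizes differ by at most 1."""
    record_ids = np.asarray(record_ids)
    labels = np.asarray(labels)
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < n_folds:
        raise ValueError(
            f"stratification infeasible: smallest class has {counts.min()} "
            f"members, need >= {n_folds}"
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    assignment: dict[str, int] = {}
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        for i in test_idx:
            assignment[str(record_ids[i])] = fold
    fa = FoldAssignment(assignment, n_folds, seed)
    fa.validate(dict(zip(map(str, record_ids), labels)))
    return fa


@dataclass
class CrossValResult:
    """Per-fold accuracies plus aggregate confusion counts for one task."""

    task: str
    fold_accuracies: np.ndarray
    train_accuracies: np.ndarray
    mean_accuracy: float
    mean_train_accuracy: float
    confusion: np.ndarray
    class_order: list[str]
    folds: FoldAssignment
    chosen_params: list[dict]


def _task_view(dataset: LabeledDataset, task: str):
    """Indices into the dataset and the score labels for a task."""
    conditions = dataset.conditions
    if task == "condition":
        return np.arange(len(dataset)), conditions
    if task == "petroleum":
        idx = np.flatnonzero(conditions == "petroleum")
        return idx, dataset.class_ids[idx]
    if task == "pesticide":
        idx = np.flatnonzero(conditions == "pesticide")
        return idx, dataset.class_ids[idx]
    if task == "end_to_end":
        return np.arange(len(dataset)), dataset.class_ids
    raise ValueError(f"task must be one of {TASKS}, got {task!r}")


def crossvalidate(
    dataset: LabeledDataset,
    feature_spec: FeatureSpec,
    classifier_spec: ClassifierSpec,
    task: str,
    n_folds: int = 10,
    folds: FoldAssignment | None = None,
    features: pd.DataFrame | None = None,
) -> CrossValResult:
    """Stratified k-fold evaluation of one feature × classifier combination.

    ``condition`` scores the 3-class soil condition over all records;
    ``petroleum`` / ``pesticide`` score subtype labels on that branch's
    true subset in isolation; ``end_to_end`` scores the full cascade's
    9-class final label, including routing errors.  A precomputed
    ``FoldAssignment`` can be shared across combinations so cells of an
    accuracy table differ only by method.  Feature extraction is per-record
    (no cross-record fitting), so the precomputed table leaks nothing; the
    scaler and the grid search run inside each training fold.
    """
    idx, score_labels = _task_view(dataset, task)
    sub = dataset.subset(list(idx))
    if features is None:
        table = featurize_dataset(sub, feature_spec)
    else:
        table = features.iloc[idx].reset_index(drop=True)
    X = feature_matrix(table)
    record_ids = sub.record_ids

    if folds is None:
        folds = make_folds(record_ids, score_labels, n_folds, classifier_spec.seed)
    folds.validate(dict(zip(record_ids, score_labels)))
    fold_of = folds.fold_of(record_ids)

    class_order = sorted(np.unique(score_labels))
    class_pos = {c: i for i, c in enumerate(class_order)}
    confusion = np.zeros((len(class_order), len(class_order)), dtype=int)
    fold_acc = np.empty(folds.n_folds)
    train_acc = np.empty(folds.n_folds)
    chosen: list[dict] = []

    for fold in range(folds.n_folds):
        test_mask = fold_of == fold
        train_mask = ~test_mask
        if task == "end_to_end":
            model = _train_cascade_from_features(
                table.loc[train_mask].reset_index(drop=True),
                feature_spec,
                classifier_spec,
            )
            pred_test = np.array(
                [t.final_label for t in _predict_rows(model, X[test_mask])]
            )
            pred_train = np.array(
                [t.final_label for t in _predict_rows(model, X[train_mask])]
            )
            chosen.append(model.chosen_hyperparams)
        else:
            stage = fit_stage(X[train_mask], score_labels[train_mask], classifier_spec)
            pred_test = stage.predict(X[test_mask])
            pred_train = stage.predict(X[train_mask])
            chosen.append(stage.params)
        truth = score_labels[test_mask]
        fold_acc[fold] = float(np.mean(pred_test == truth))
        train_acc[fold] = float(np.mean(pred_train == score_labels[train_mask]))
        for t, p in zip(truth, pred_test):
            confusion[class_pos[t], class_pos[p]] += 1

    return CrossValResult(
        task=task,
        fold_accuracies=fold_acc,
        train_accuracies=train_acc,
        mean_accuracy=float(fold_acc.mean()),
        mean_train_accuracy=float(train_acc.mean()),
        confusion=confusion,
        class_order=list(class_order),
        folds=folds,
        chosen_params=chosen,
    )


# ---------------------------------------------------------------------------
# Model persistence
# ---------------------------------------------------------------------------


def save_cascade(model: CascadeModel, path: str | Path) -> Path:
    """Serialise a fitted cascade (single archive, versioned)."""
    path = Path(path)
    joblib.dump({"format_version": MODEL_FORMAT_VERSION, "model": model}, path)
    return path


def load_cascade(path: str | Path) -> CascadeModel:
    payload = joblib.load(path)
    version = payload.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"unsupported model archive version {version!r}, "
            f"expected {MODEL_FORMAT_VERSION!r}"
        )
    return payload["model"]
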