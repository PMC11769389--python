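"""Result surfaces: feature × classifier accuracy tables, confusion
matrices, and 2-D LDA/PCA projections of odor fingerprints.

The accuracy table mirrors the standard layout of e-nose comparison
studies: one row per classifier (SVM, RF) plus an ``Average`` row, one
column per feature method (Ave, FFT, IV, Max, PCF, WT) plus an ``Average``
column, cells in percent.  All twelve cells of one table share a single
fold assignment, so they differ only by method.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.linalg
from sklearn.decomposition import PCA

from .dataset_io import LabeledDataset, provenance_hash
from .features import (
    FEATURE_METHODS,
    FeatureSpec,
    default_feature_specs,
    feature_matrix,
    featurize_dataset,
)
from .recognition import (
    ClassifierSpec,
    CrossValResult,
    FoldAssignment,
    _task_view,
    crossvalidate,
    default_classifier_specs,
    make_folds,
)
from .synthetic_data import DEFAULT_SEED


def confusion_matrix(
    true_labels: Sequence[str],
    predicted_labels: Sequence[str],
    class_order: Sequence[str],
) -> np.ndarray:
    """Count matrix with entry (i, j) = truth i predicted as j."""
    truth = np.asarray(true_labels)
    pred = np.asarray(predicted_labels)
    if truth.shape != pred.shape:
        raise ValueError(
            f"label vectors differ in length: {truth.shape} vs {pred.shape}"
        )
    pos = {c: i for i, c in enumerate(class_order)}
    unknown = [l for l in np.unique(np.concatenate([truth, pred])) if l not in pos]
    if unknown:
        raise ValueError(f"labels outside class_order: {unknown}")
    out = np.zeros((len(class_order), len(class_order)), dtype=int)
    for t, p in zip(truth, pred):
        out[pos[t], pos[p]] += 1
    return out


@dataclass
class EvaluationReport:
    """Accuracy table (percent) plus confusions for one task."""

    task: str
    table: pd.DataFrame
    train_table: pd.DataFrame
    confusions: dict[str, np.ndarray]
    class_order: list[str]
    fold_seed: int
    config_provenance: str
    results: dict[str, CrossValResult]

    def to_json(self, path: str | Path) -> Path:
        """Deterministic JSON serialisation (sorted keys, plain lists)."""
        payload = {
            "task": self.task,
            "accuracy_table_pct": {
                row: {col: self.table.loc[row, col] for col in self.table.columns}
                for row in self.table.index
            },
            "train_accuracy_table_pct": {
                row: {
                    col: self.train_table.loc[row, col]
                    for col in self.train_table.columns
                }
                for row in self.train_table.index
            },
            "class_order": self.class_order,
            "confusions": {k: v.tolist() for k, v in self.confusions.items()},
            "fold_seed": self.fold_seed,
            "config_provenance": self.config_provenance,
        }
        path = Path(path)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")
        return path

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.table.to_csv(path, index_label="Classifiers", float_format="%.2f")
        return path


def combo_accuracy_table(
    dataset: LabeledDataset,
    task: str,
    feature_specs: Sequence[FeatureSpec] | None = None,
    classifier_specs: Sequence[ClassifierSpec] | None = None,
    n_folds: int = 10,
    fold_seed: int = DEFAULT_SEED,
) -> EvaluationReport:
    """Cross-validate every feature × classifier combination on one task.

    Returns the per-cell mean test accuracies in percent with the
    ``Average`` row/column appended, matching the published table layout;
    the grand average sits at (Average, Average).
    """
    feature_specs = list(feature_specs or default_feature_specs())
    classifier_specs = list(classifier_specs or default_classifier_specs(fold_seed))

    idx, score_labels = _task_view(dataset, task)
    sub = dataset.subset(list(idx))
    folds = make_folds(sub.record_ids, score_labels, n_folds, fold_seed)

    methods = [fs.method for fs in feature_specs]
    kinds = [cs.kind for cs in classifier_specs]
    table = pd.DataFrame(index=kinds, columns=methods, dtype=float)
    train_table = pd.DataFrame(index=kinds, columns=methods, dtype=float)
    confusions: dict[str, np.ndarray] = {}
    results: dict[str, CrossValResult] = {}
    class_order: list[str] = []

    for fs in feature_specs:
        features = featurize_dataset(dataset, fs)
        for cs in classifier_specs:
            res = crossvalidate(
                dataset, fs, cs, task, n_folds=n_folds, folds=folds, features=features
            )
            key = f"{cs.kind}|{fs.method}"
            table.loc[cs.kind, fs.method] = 100.0 * res.mean_accuracy
            train_table.loc[cs.kind, fs.method] = 100.0 * res.mean_train_accuracy
            confusions[key] = res.confusion
            results[key] = res
            class_order = res.class_order

    for t in (table, train_table):
        t["Average"] = t.mean(axis=1)
        t.loc["Average"] = t.mean(axis=0)

    return EvaluationReport(
        task=task,
        table=table,
        train_table=train_table,
        confusions=confusions,
        class_order=class_order,
        fold_seed=fold_seed,
        config_provenance=provenance_hash(
            {"dataset": dataset.provenance, "task": task, "fold_seed": fold_seed}
        ),
        results=results,
    )


# ---------------------------------------------------------------------------
# Projections
# ---------------------------------------------------------------------------


@dataclass
class Projection2D:
    """2-D embedding of a feature table for visual class separability."""

    method: str  # "LDA" | "PCA"
    coordinates: np.ndarray
    labels: np.ndarray
    explained: np.ndarray


def pca_project(features: pd.DataFrame, labels: Sequence[str] | None = None) -> Projection2D:
    """Project centred features onto the top-2 principal axes.

    ``explained`` holds the top-2 eigenvalue shares of the sample
    covariance (non-increasing).
    """
    X = feature_matrix(features)
    if X.shape[0] < 3 or X.shape[1] < 2:
        raise ValueError(
            f"need >= 3 records and >= 2 feature columns, got {X.shape}"
        )
    if np.allclose(X.std(axis=0), 0):
        raise ValueError("degenerate feature set: zero variance in every column")
    pca = PCA(n_components=2, svd_solver="full", random_state=0)
    coords = pca.fit_transform(X)
    if labels is None:
        labels = features["class_id"].to_numpy() if "class_id" in features else np.array([""] * len(X))
    return Projection2D(
        "PCA", coords, np.asarray(labels), pca.explained_variance_ratio_.copy()
    )


def lda_project(
    features: pd.DataFrame,
    labels: Sequence[str],
    n_components: int = 2,
    ridge: float | None = None,
) -> Projection2D:
    """Fisher discriminant projection onto the top generalized eigenvectors.

    Solves S_b v = λ (S_w + ridge·I) v; the default ridge is
    1e-6 · trace(S_w)/d, which keeps the within-class scatter invertible
    for high-dimensional feature tables.  At most C − 1 discriminants
    exist for C classes.
    """
    X = feature_matrix(features)
    y = np.asarray(labels)
    classes = np.unique(y)
    if n_components > len(classes) - 1:
        raise ValueError(
            f"LDA yields at most {len(classes) - 1} discriminant axes for "
            f"{len(classes)} classes; {n_components} requested"
        )
    mean = X.mean(axis=0)
    d = X.shape[1]
    S_w = np.zeros((d, d))
    S_b = np.zeros((d, d))
    for c in classes:
        Xc = X[y == c]
        mc = Xc.mean(axis=0)
        diff = Xc - mc
        S_w += diff.T @ diff
        gap = (mc - mean)[:, None]
        S_b += len(Xc) * (gap @ gap.T)
    if ridge is None:
        ridge = 1e-6 * np.trace(S_w) / d
    if ridge <= 0 and np.linalg.matrix_rank(S_w) < d:
        raise ValueError(
            "singular within-class scatter; pass a positive ridge to regularize"
        )
    S_w_reg = S_w + ridge * np.eye(d)
    eigvals, eigvecs = scipy.linalg.eigh(S_b, S_w_reg)
    order = np.argsort(eigvals)[::-1][:n_components]
    vals = np.clip(eigvals[order], 0, None)
    coords = X @ eigvecs[:, order]
    total = eigvals[eigvals > 0].sum()
    explained = vals / total if total > 0 else np.zeros_like(vals)
    return Projection2D("LDA", coords, y, explained)


def save_projection(proj: Projection2D, path: str | Path) -> Path:
    """Write projection coordinates as delimited text with a label column."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "dim1": proj.coordinates[:, 0],
            "dim2": proj.coordinates[:, 1] if proj.coordinates.shape[1] > 1 else 0.0,
            "label": proj.labels,
        }
    )
    df.to_csv(path, index=False, float_format="%.9g")
    return path


def plot_projection(proj: Projection2D, path: str | Path, title: str = "") -> Path:
    """Optional scatter rendering of a 2-D projection (PNG/SVG by suffix)."""
    from matplotlib.figure import Figure

    fig = Figure(figsize=(6, 5))
    ax = fig.add_subplot(111)
    for lab in np.unique(proj.labels):
        mask = proj.labels == lab
        ax.scatter(
            proj.coordinates[mask, 0],
            proj.coordinates[mask, 1],
            s=14,
            label=str(lab),
            alpha=0.8,
        )
    ax.set_xlabel(f"{proj.method} 1")
    ax.set_ylabel(f"{proj.method} 2")
    if title:
        ax.set_title(title)
    ax.legend(fontsize=7, markerscale=1.2)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    return Path(path)
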