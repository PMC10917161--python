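"""Multi-scale feature assembly and SVM evaluation under 10-fold CV.

Per-scale feature vectors hold one metric value per node (84/58/16/6/4
columns for the packaged hierarchy); the combined vector concatenates all
scales, finest first (168 columns). Labels are +1 patient / -1 control.
Evaluation uses a linear-kernel SVM (C = 1 by default) under stratified
k-fold cross-validation with features standardised on training-fold
statistics only; specificity, sensitivity and accuracy come from the
confusion counts pooled across folds, with patient as the positive class.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .atlas import AtlasHierarchy
from .errors import AssemblyError, StratificationError

PATIENT_LABEL = 1
CONTROL_LABEL = -1


@dataclass
class FeatureMatrix:
    """Subjects x features with (scale, node_id, metric_name) column names."""

    X: np.ndarray
    feature_names: list[tuple[int, int, str]]
    labels: np.ndarray               # +1 patient / -1 control
    subject_ids: list[str]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.X.shape != (len(self.subject_ids), len(self.feature_names)):
            raise AssemblyError("feature matrix shape does not match names/subjects")
        if not np.all(np.isin(self.labels, [PATIENT_LABEL, CONTROL_LABEL])):
            raise AssemblyError("labels must be +1 (patient) or -1 (control)")
        if not np.all(np.isfinite(self.X)):
            raise AssemblyError("feature matrix contains missing values")

    @property
    def n_features(self) -> int:
        return self.X.shape[1]


@dataclass
class ClassificationReport:
    """Pooled cross-validated performance, as percentages."""

    specificity: float
    sensitivity: float
    accuracy: float
    fold_confusions: list[dict]      # per fold: tp, tn, fp, fn
    configuration: dict

    @property
    def pooled_confusion(self) -> dict:
        keys = ("tp", "tn", "fp", "fn")
        return {k: sum(f[k] for f in self.fold_confusions) for k in keys}

    def to_dict(self) -> dict:
        return {
            "specificity": self.specificity,
            "sensitivity": self.sensitivity,
            "accuracy": self.accuracy,
            "pooled_confusion": self.pooled_confusion,
            "fold_confusions": self.fold_confusions,
            "configuration": self.configuration,
        }


def summarize_confusion(tp: int, tn: int, fp: int, fn: int) -> dict:
    """Specificity, sensitivity, accuracy (percent) from confusion counts."""
    total = tp + tn + fp + fn
    return {
        "specificity": 100.0 * tn / (tn + fp) if tn + fp else float("nan"),
        "sensitivity": 100.0 * tp / (tp + fn) if tp + fn else float("nan"),
        "accuracy": 100.0 * (tp + tn) / total if total else float("nan"),
    }


def assemble_features(metric_table: pd.DataFrame, metric_name: str,
                      scales: Union[int, str], h: AtlasHierarchy,
                      groups: dict[str, str]) -> FeatureMatrix:
    """Build a feature matrix from a tidy metric table.

    ``scales`` is a single scale index or ``"all"`` for the concatenation
    (finest scale first, nodes in atlas order within each scale).
    """
    if scales == "all":
        scale_list = list(range(1, h.n_scales + 1))
    else:
        scale_list = [int(scales)]
    sub = metric_table[metric_table["metric_name"] == metric_name]
    if sub.empty:
        raise AssemblyError(f"no rows for metric '{metric_name}'")
    subject_ids = sorted(sub["subject_id"].unique())

    lookup = {(r.subject_id, r.scale, r.node_id): r.value
              for r in sub.itertuples()}
    names: list[tuple[int, int, str]] = []
    for s in scale_list:
        names.extend((s, int(nid), metric_name) for nid in h.node_ids(s))
    X = np.empty((len(subject_ids), len(names)))
    for i, sid in enumerate(subject_ids):
        for j, (s, nid, _) in enumerate(names):
            try:
                X[i, j] = lookup[(sid, s, nid)]
            except KeyError:
                raise AssemblyError(
                    f"subject {sid} lacks {metric_name} at scale {s}, node {nid}"
                ) from None
    labels = []
    for sid in subject_ids:
        try:
            g = groups[sid]
        except KeyError:
            raise AssemblyError(f"subject {sid} has no group label") from None
        labels.append(PATIENT_LABEL if g == "patient" else CONTROL_LABEL)
    return FeatureMatrix(X=X, feature_names=names, labels=np.array(labels),
                         subject_ids=subject_ids)


def crossval_svm(fm: FeatureMatrix, k_folds: int = 10, seed: int = 0,
                 kernel: str = "linear", C: float = 1.0) -> ClassificationReport:
    """Stratified k-fold SVM evaluation with pooled confusion counts."""
    n = len(fm.subject_ids)
    if n < k_folds:
        raise StratificationError(f"{n} subjects cannot fill {k_folds} folds")
    classes, counts = np.unique(fm.labels, return_counts=True)
    if classes.size < 2:
        raise StratificationError("both groups must be present")
    if counts.min() < k_folds:
        raise StratificationError(
            "smallest group is smaller than the fold count; folds cannot be stratified")

    # canonical subject order: fold assignment depends only on (ids, seed)
    canon = np.argsort(np.asarray(fm.subject_ids), kind="stable")
    X, y = fm.X[canon], fm.labels[canon]
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    folds = []
    for train_idx, test_idx in skf.split(X, y):
        y_train = y[train_idx]
        if np.unique(y_train).size < 2:
            raise StratificationError("a training fold contains a single class")
        scaler = StandardScaler().fit(X[train_idx])
        clf = SVC(kernel=kernel, C=C)
        clf.fit(scaler.transform(X[train_idx]), y_train)
        pred = clf.predict(scaler.transform(X[test_idx]))
        truth = y[test_idx]
        folds.append({
            "tp": int(np.sum((pred == PATIENT_LABEL) & (truth == PATIENT_LABEL))),
            "tn": int(np.sum((pred == CONTROL_LABEL) & (truth == CONTROL_LABEL))),
            "fp": int(np.sum((pred == PATIENT_LABEL) & (truth == CONTROL_LABEL))),
            "fn": int(np.sum((pred == CONTROL_LABEL) & (truth == PATIENT_LABEL))),
        })
    pooled = {k: sum(f[k] for f in folds) for k in ("tp", "tn", "fp", "fn")}
    perf = summarize_confusion(**pooled)
    return ClassificationReport(
        specificity=perf["specificity"],
        sensitivity=perf["sensitivity"],
        accuracy=perf["accuracy"],
        fold_confusions=folds,
        configuration={"kernel": kernel, "C": C, "k_folds": k_folds,
                       "seed": seed, "standardized": "per training fold",
                       "pooling": "confusion counts pooled across folds",
                       "n_features": fm.n_features},
    )


def write_feature_tsv(fm: FeatureMatrix, path) -> None:
    """Features as TSV with 'scale:node:metric' column headers."""
    cols = [f"{s}:{nid}:{m}" for s, nid, m in fm.feature_names]
    df = pd.DataFrame(fm.X, index=fm.subject_ids, columns=cols)
    df.insert(0, "label", fm.labels)
    df.to_csv(path, sep="\t", index_label="subject_id", float_format="%.8g")
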