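"""Subject-wise evaluation protocol.

Cross-validation uses an overlapping-window fold rule over the ordered
subject list S_1..S_M: the test set of fold k is

    V_k = {S_i, S_{i+1}, S_{i+2}},   i = 2k - 1,

so with 21 subjects and 10 folds every subject is tested at least once
while train and test subjects stay mutually exclusive within each fold.
Accuracy is reported overall and as a 5x5 row-percentage confusion matrix
in the fixed class order (scissor, spastic, steppage, normal, propulsive).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import CLASS_LABELS, GaitClassifier, ModelConfig

#: gait type -> pathology vocabulary used by at-home capture datasets
GAIT_TO_PATHOLOGY = {
    "scissor": "diplegic",
    "spastic": "hemiplegic",
    "steppage": "neuropathic",
    "normal": "healthy",
    "propulsive": "Parkinsonian",
}
PATHOLOGY_TO_GAIT = {v: k for k, v in GAIT_TO_PATHOLOGY.items()}


@dataclass(frozen=True)
class FoldScheme:
    """Subject-wise folds under the overlapping-window rule."""

    subject_ids: tuple
    n_folds: int

    def __post_init__(self):
        if len(self.subject_ids) < 2 * self.n_folds + 1:
            raise ValueError(
                f"{self.n_folds} folds need at least {2 * self.n_folds + 1} "
                f"subjects, got {len(self.subject_ids)}")
        if len(set(self.subject_ids)) != len(self.subject_ids):
            raise ValueError("subject ids must be unique")

    def test_subjects(self, k: int) -> tuple:
        """V_k = {S_i, S_i+1, S_i+2} with i = 2k - 1 (k is 1-based)."""
        if not 1 <= k <= self.n_folds:
            raise ValueError(f"fold index must be in 1..{self.n_folds}")
        i = 2 * k - 1
        return tuple(self.subject_ids[i - 1:i + 2])

    def train_subjects(self, k: int) -> tuple:
        test = set(self.test_subjects(k))
        return tuple(s for s in self.subject_ids if s not in test)

    def folds(self):
        for k in range(1, self.n_folds + 1):
            yield k, self.train_subjects(k), self.test_subjects(k)


def make_folds(subject_ids, n_folds: int = 10) -> FoldScheme:
    """Build the overlapping-window fold scheme over an ordered subject list."""
    return FoldScheme(subject_ids=tuple(subject_ids), n_folds=n_folds)


@dataclass
class EvaluationReport:
    """Accuracy, per-class accuracy and a row-percentage confusion matrix."""

    overall_accuracy: float                  # percent
    per_class_accuracy: dict
    confusion: pd.DataFrame                  # rows true, cols predicted, %
    fold_accuracies: list = field(default_factory=list)
    n_test: int = 0

    def to_dict(self):
        return {
            "overall_accuracy": self.overall_accuracy,
            "per_class_accuracy": self.per_class_accuracy,
            "confusion_matrix": {
                "row_order": list(self.confusion.index),
                "col_order": list(self.confusion.columns),
                "rows_percent": [[None if np.isnan(v) else float(v) for v in row]
                                 for row in self.confusion.to_numpy()],
            },
            "fold_accuracies": self.fold_accuracies,
            "n_test": self.n_test,
        }

    def save_json(self, path):
        with open(path, "w") as f:
            json.dump(self.to_dict(), f, indent=2)

    def format_grid(self) -> str:
        """A printable true-class x predicted-class percentage grid."""
        lines = [f"overall accuracy: {self.overall_accuracy:.1f}%", ""]
        lines.append(self.confusion.round(1).to_string(na_rep="--"))
        return "\n".join(lines)


def confusion_matrix(truths, predictions, labels=CLASS_LABELS) -> pd.DataFrame:
    """Row-percentage confusion matrix: entry (r, c) is the percentage of
    true-class-r samples predicted as class c.  Rows with zero support are
    reported as NaN (undefined), not zero."""
    truths = list(truths)
    predictions = list(predictions)
    if len(truths) != len(predictions):
        raise ValueError("truths and predictions must have equal length")
    mat = np.full((len(labels), len(labels)), np.nan)
    t = np.asarray(truths)
    p = np.asarray(predictions)
    for r, lab in enumerate(labels):
        support = t == lab
        if support.sum() == 0:
            continue
        for c, plab in enumerate(labels):
            mat[r, c] = 100.0 * np.mean(p[support] == plab)
    return pd.DataFrame(mat, index=list(labels), columns=list(labels))


def _report_from_predictions(truths, predictions, labels=CLASS_LABELS,
                             fold_accuracies=None) -> EvaluationReport:
    truths = list(truths)
    predictions = list(predictions)
    conf = confusion_matrix(truths, predictions, labels)
    acc = 100.0 * np.mean(np.asarray(truths) == np.asarray(predictions))
    per_class = {lab: (float(conf.loc[lab, lab])
                       if not np.isnan(conf.loc[lab, lab]) else None)
                 for lab in labels}
    if fold_accuracies:
        overall = float(np.mean(fold_accuracies))
    else:
        overall = float(acc)
    return EvaluationReport(overall_accuracy=overall,
                            per_class_accuracy=per_class,
                            confusion=conf,
                            fold_accuracies=list(fold_accuracies or []),
                            n_test=len(truths))


def _default_classifier_factory(config: ModelConfig):
    def factory(images, labels):
        clf = GaitClassifier(config)
        clf.train(images, labels)
        return clf
    return factory


def _predict_labels(clf, images):
    proba = clf.predict_proba(images)
    return [CLASS_LABELS[i] for i in proba.argmax(axis=1)]


def cross_validate(manifest: pd.DataFrame, representations: dict,
                   config: ModelConfig, scheme: FoldScheme,
                   classifier_factory=None) -> EvaluationReport:
    """Subject-wise k-fold cross-validation over a manifest.

    ``representations`` maps each manifest ``sequence_uri`` to a 224x224
    energy image (array or GaitRepresentation).  For every fold a fresh
    classifier is trained on the non-test subjects' sequences and evaluated
    on the test subjects'; a sequence's prediction is the argmax of its
    whole-sequence representation.  Mean fold accuracy (unweighted — the
    window rule makes folds overlap) and a pooled confusion matrix are
    reported.  ``classifier_factory(images, labels) -> classifier`` may
    replace the CNN (any object with ``predict_proba``).
    """
    missing = set(manifest.sequence_uri) - set(representations)
    if missing:
        raise ValueError(f"{len(missing)} manifest sequences lack representations")
    counts = manifest.groupby("subject_id").size()
    empty = [s for s in scheme.subject_ids if counts.get(s, 0) == 0]
    if empty:
        raise ValueError(f"subjects without sequences: {empty}")
    factory = classifier_factory or _default_classifier_factory(config)

    fold_accs, all_true, all_pred = [], [], []
    for k, train_subj, test_subj in scheme.folds():
        if set(train_subj) & set(test_subj):
            raise AssertionError("train/test subjects overlap within a fold")
        tr = manifest[manifest.subject_id.isin(train_subj)]
        te = manifest[manifest.subject_id.isin(test_subj)]
        clf = factory([representations[u] for u in tr.sequence_uri],
                      list(tr.gait_type))
        pred = _predict_labels(clf, [representations[u] for u in te.sequence_uri])
        true = list(te.gait_type)
        fold_accs.append(100.0 * np.mean(np.asarray(pred) == np.asarray(true)))
        all_true.extend(true)
        all_pred.extend(pred)
    return _report_from_predictions(all_true, all_pred,
                                    fold_accuracies=fold_accs)


def cross_dataset_eval(train_manifest: pd.DataFrame, train_representations: dict,
                       test_manifest: pd.DataFrame, test_representations: dict,
                       config: ModelConfig, label_map: dict | None = None,
                       classifier_factory=None) -> EvaluationReport:
    """Train once on dataset A, evaluate on dataset B.

    ``label_map`` translates the test dataset's label vocabulary into the
    training gait types (defaults to the pathology mapping: diplegic ->
    scissor, hemiplegic -> spastic, neuropathic -> steppage, healthy ->
    normal, Parkinsonian -> propulsive); the report's class names are the
    test-domain names.
    """
    label_map = dict(label_map) if label_map is not None else dict(PATHOLOGY_TO_GAIT)
    test_labels = list(test_manifest.gait_type)
    unmapped = {lab for lab in test_labels
                if lab not in label_map and lab not in CLASS_LABELS}
    if unmapped:
        raise ValueError(f"unmappable test labels: {sorted(unmapped)}")

    factory = classifier_factory or _default_classifier_factory(config)
    clf = factory([train_representations[u] for u in train_manifest.sequence_uri],
                  list(train_manifest.gait_type))
    pred_gait = _predict_labels(
        clf, [test_representations[u] for u in test_manifest.sequence_uri])

    inverse = {v: k for k, v in label_map.items()}
    report_labels = tuple(inverse.get(lab, lab) for lab in CLASS_LABELS)
    true_mapped = [label_map.get(lab, lab) for lab in test_labels]
    pred = [inverse.get(lab, lab) for lab in pred_gait]
    true = [inverse.get(lab, lab) for lab in true_mapped]
    return _report_from_predictions(true, pred, labels=report_labels)
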