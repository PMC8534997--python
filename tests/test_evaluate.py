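"""Evaluation protocol: fold rule, confusion matrices, cross-validation."""

import numpy as np
import pandas as pd
import pytest

from gaitkit import evaluate as ev
from gaitkit.gaitsim import generate_manifest
from gaitkit.model import CLASS_LABELS


@pytest.fixture(scope="module")
def subjects():
    return [f"S{i}" for i in range(1, 22)]


class TestMakeFolds:

    def test_first_fold_tests_first_three_subjects(self, subjects):
        scheme = ev.make_folds(subjects, n_folds=10)
        assert scheme.test_subjects(1) == ("S1", "S2", "S3")

    def test_last_fold_tests_last_three_subjects(self, subjects):
        scheme = ev.make_folds(subjects, n_folds=10)
        assert scheme.test_subjects(10) == ("S19", "S20", "S21")

    def test_union_of_test_sets_covers_all_subjects(self, subjects):
        scheme = ev.make_folds(subjects, n_folds=10)
        union = set()
        for k, _, test in scheme.folds():
            union |= set(test)
        assert union == set(subjects)

    def test_train_and_test_subjects_disjoint_per_fold(self, subjects):
        scheme = ev.make_folds(subjects, n_folds=10)
        for k, train, test in scheme.folds():
            assert not set(train) & set(test)
            assert set(train) | set(test) == set(subjects)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            ev.make_folds(["S1", "S2", "S3"], n_folds=2)

    def test_duplicate_subjects_rejected(self):
        with pytest.raises(ValueError):
            ev.make_folds(["S1"] * 5, n_folds=1)


class TestConfusionMatrix:
    def test_perfect_predictions_give_identity(self):
        labels = list(CLASS_LABELS) * 3
        conf = ev.confusion_matrix(labels, labels)
        np.testing.assert_array_equal(conf.to_numpy(),
                                      100.0 * np.eye(5))

    def test_collapsed_predictions_fill_one_column(self):
        truths = list(CLASS_LABELS)
        preds = ["scissor"] * 5
        conf = ev.confusion_matrix(truths, preds)
        np.testing.assert_array_equal(conf["scissor"].to_numpy(),
                                      np.full(5, 100.0))

    def test_matches_hand_computed_counts(self):
        # 20 labelled pairs counted by hand
        truths = (["scissor"] * 4 + ["spastic"] * 4 + ["steppage"] * 4
                  + ["normal"] * 4 + ["propulsive"] * 4)
        preds = (["scissor", "scissor", "spastic", "propulsive"]
                 + ["spastic"] * 3 + ["scissor"]
                 + ["steppage"] * 4
                 + ["normal"] * 3 + ["steppage"]
                 + ["propulsive"] * 2 + ["scissor", "scissor"])
        conf = ev.confusion_matrix(truths, preds)
        assert conf.loc["scissor", "scissor"] == 50.0
        assert conf.loc["scissor", "spastic"] == 25.0
        assert conf.loc["scissor", "propulsive"] == 25.0
        assert conf.loc["spastic", "spastic"] == 75.0
        assert conf.loc["steppage", "steppage"] == 100.0
        assert conf.loc["normal", "normal"] == 75.0
        assert conf.loc["propulsive", "propulsive"] == 50.0
        assert conf.loc["propulsive", "scissor"] == 50.0
        np.testing.assert_allclose(conf.sum(axis=1).to_numpy(),
                                   np.full(5, 100.0))

    def test_zero_support_rows_are_undefined_not_zero(self):
        conf = ev.confusion_matrix(["normal"], ["normal"])
        assert np.isnan(conf.loc["scissor"].to_numpy()).all()
        assert conf.loc["normal", "normal"] == 100.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ev.confusion_matrix(["normal"], ["normal", "spastic"])


# ---------------------------------------------------------------------------
# cross-validation mechanics with a fast nearest-centroid classifier


class _CentroidClassifier:
    """Nearest-centroid stand-in honouring the classifier interface."""

    def __init__(self, images, labels):
        self.centroids = {}
        X = np.stack([np.asarray(im, dtype=float).ravel() for im in images])
        for lab in set(labels):
            idx = [i for i, l in enumerate(labels) if l == lab]
            self.centroids[lab] = X[idx].mean(axis=0)

    def predict_proba(self, images):
        out = np.full((len(images), len(CLASS_LABELS)), -np.inf)
        for i, im in enumerate(images):
            v = np.asarray(im, dtype=float).ravel()
            for j, lab in enumerate(CLASS_LABELS):
                if lab in self.centroids:
                    out[i, j] = -np.linalg.norm(v - self.centroids[lab])
        return out


def _centroid_factory(images, labels):
    return _CentroidClassifier(images, labels)


def _pattern_representations(manifest, noise=0.05, seed=0, shift=0.0):
    """Small class-coded images: one separable pattern per gait type."""
    rng = np.random.default_rng(seed)
    bases = {lab: np.random.default_rng(100 + i).random((16, 16))
             for i, lab in enumerate(CLASS_LABELS)}
    return {row.sequence_uri: bases[row.gait_type] + shift
            + noise * rng.random((16, 16))
            for row in manifest.itertuples()}


@pytest.fixture(scope="module")
def cv_setup():
    manifest = generate_manifest(21, seed=0)
    reps = _pattern_representations(manifest)
    subjects = list(pd.unique(manifest.subject_id))
    scheme = ev.make_folds(subjects, n_folds=10)
    return manifest, reps, scheme


class TestCrossValidate:
    def test_separable_classes_recovered_above_90(self, cv_setup):
        manifest, reps, scheme = cv_setup
        report = ev.cross_validate(manifest, reps, None, scheme,
                                   classifier_factory=_centroid_factory)
        assert report.overall_accuracy >= 90.0
        assert len(report.fold_accuracies) == 10

    def test_permuted_labels_land_near_chance(self, cv_setup):
        manifest, reps, scheme = cv_setup
        shuffled = manifest.copy()
        rng = np.random.default_rng(7)
        shuffled["gait_type"] = rng.permutation(shuffled.gait_type.values)
        report = ev.cross_validate(shuffled, reps, None, scheme,
                                   classifier_factory=_centroid_factory)
        assert 10.0 <= report.overall_accuracy <= 30.0

    def test_missing_representations_rejected(self, cv_setup):
        manifest, reps, scheme = cv_setup
        partial = dict(list(reps.items())[:-5])
        with pytest.raises(ValueError):
            ev.cross_validate(manifest, partial, None, scheme,
                              classifier_factory=_centroid_factory)

    def test_degenerate_scheme_with_duplicate_subjects_rejected(self):
        with pytest.raises(ValueError):
            ev.FoldScheme(subject_ids=("A", "A", "A"), n_folds=1)

    def test_accuracy_is_support_weighted_mean_of_recalls(self):
        rng = np.random.default_rng(0)
        truths = list(rng.choice(CLASS_LABELS, size=200, p=[.4, .3, .1, .1, .1]))
        preds = list(rng.choice(CLASS_LABELS, size=200))
        accuracy = 100.0 * np.mean(np.asarray(truths) == np.asarray(preds))
        conf = ev.confusion_matrix(truths, preds)
        support = pd.Series(truths).value_counts()
        weighted = sum(support[lab] * conf.loc[lab, lab]
                       for lab in CLASS_LABELS) / support.sum()
        assert accuracy == pytest.approx(weighted)


class TestCrossDataset:
    def _pathology_manifest(self, n_sessions, seed):
        m = generate_manifest(n_sessions, seed=seed)
        m = m.copy()
        m["gait_type"] = m["gait_type"].map(ev.GAIT_TO_PATHOLOGY)
        return m

    def test_domain_shift_stays_above_chance(self):
        train_m = generate_manifest(3, seed=1)
        test_m = self._pathology_manifest(2, seed=2)
        train_reps = _pattern_representations(train_m, noise=0.05, seed=3)
        noisy = generate_manifest(2, seed=2)
        test_reps = _pattern_representations(noisy, noise=0.4, seed=4,
                                             shift=0.1)
        test_reps = {u: test_reps[u] for u in noisy.sequence_uri}
        report = ev.cross_dataset_eval(train_m, train_reps, test_m, test_reps,
                                       None,
                                       classifier_factory=_centroid_factory)
        assert report.overall_accuracy > 40.0  # chance is 20%

    def test_report_uses_test_domain_class_names(self):
        train_m = generate_manifest(2, seed=5)
        test_m = self._pathology_manifest(1, seed=6)
        train_reps = _pattern_representations(train_m)
        test_reps = _pattern_representations(generate_manifest(1, seed=6))
        report = ev.cross_dataset_eval(train_m, train_reps, test_m, test_reps,
                                       None,
                                       classifier_factory=_centroid_factory)
        assert set(report.confusion.index) == set(ev.GAIT_TO_PATHOLOGY.values())

    def test_identical_train_test_memorizes(self):
        m = generate_manifest(2, seed=8)
        reps = _pattern_representations(m, noise=0.01)
        report = ev.cross_dataset_eval(m, reps, m, reps, None,
                                       label_map={},
                                       classifier_factory=_centroid_factory)
        assert report.overall_accuracy == 100.0

    def test_unmappable_label_rejected(self):
        train_m = generate_manifest(1, seed=9)
        test_m = generate_manifest(1, seed=9).copy()
        test_m["gait_type"] = "waddling"
        reps = _pattern_representations(generate_manifest(1, seed=9))
        with pytest.raises(ValueError):
            ev.cross_dataset_eval(train_m, reps, test_m, reps, None,
                                  classifier_factory=_centroid_factory)
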