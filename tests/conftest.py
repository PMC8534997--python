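"""Shared fixtures: synthetic walkers and the class-recovery experiment.

The expensive artifacts (the 5-class GEI dataset and the CNNs trained on
it) are session-scoped so the class-recovery and explanation tests share
one computation.
"""

from __future__ import annotations

import numpy as np
import pytest

from gaitkit import gaitsim
from gaitkit.datasets import subject_split, synthetic_energy_images
from gaitkit.model import CLASS_LABELS, GaitClassifier, ModelConfig
from gaitkit.sequences import SilhouetteSequence

#: run sizes of the class-recovery experiment (also used by the acceptance
#: script): 40 sequences per class over 10 subjects, CNN trained 8 epochs
#: in batches of 16.
N_PER_CLASS = 40
DATASET_SEED = 11
HELD_OUT_SUBJECTS = ("subj08", "subj09")
TRAIN_EPOCHS = 8
TRAIN_BATCH = 16
TRAIN_SEEDS = (0, 1, 2)


@pytest.fixture(scope="session")
def walker_sequence():
    """One deterministic normal-gait walker with RGB frames."""
    cfg = gaitsim.WalkerConfig(gait_type="normal", frames_per_cycle=20,
                               n_cycles=2, seed=42)
    return gaitsim.generate_walker_sequence(cfg)


@pytest.fixture(scope="session")
def gei_dataset():
    """The 5-class x 40-sequence synthetic GEI set with subject ids."""
    X, y, subj = synthetic_energy_images(N_PER_CLASS, seed=DATASET_SEED)
    return X, y, subj


def heldout_accuracy(clf, X, y, test_mask):
    proba = clf.predict_proba(list(X[test_mask]))
    truth = [lab for lab, m in zip(y, test_mask) if m]
    return float(np.mean([CLASS_LABELS[i] == t
                          for i, t in zip(proba.argmax(axis=1), truth)]))


@pytest.fixture(scope="session")
def class_recovery(gei_dataset):
    """Train the CNN on the synthetic set for three seeds plus a label-
    permutation null; returns accuracies and the trained classifiers."""
    X, y, subj = gei_dataset
    train_mask, test_mask = subject_split(subj, HELD_OUT_SUBJECTS)
    out = {"accuracies": {}, "classifiers": {}, "test_mask": test_mask,
           "train_mask": train_mask}
    train_labels = [lab for lab, m in zip(y, train_mask) if m]
    for seed in TRAIN_SEEDS:
        clf = GaitClassifier(ModelConfig(seed=seed, epochs=TRAIN_EPOCHS, batch_size=TRAIN_BATCH))
        clf.train(list(X[train_mask]), train_labels, validation_fraction=0.15)
        out["classifiers"][seed] = clf
        out["accuracies"][seed] = heldout_accuracy(clf, X, y, test_mask)
    # null: same training with permuted labels
    rng = np.random.default_rng(123)
    y_perm = list(rng.permutation(y))
    clf0 = GaitClassifier(ModelConfig(seed=TRAIN_SEEDS[0], epochs=TRAIN_EPOCHS,
                                      batch_size=TRAIN_BATCH))
    clf0.train(list(X[train_mask]),
               [lab for lab, m in zip(y_perm, train_mask) if m],
               validation_fraction=0.15)
    out["null_accuracy"] = heldout_accuracy(clf0, X, y_perm, test_mask)
    return out


@pytest.fixture(scope="session")
def silhouette_from_walker(walker_sequence):
    return SilhouetteSequence(walker_sequence.truth_masks, fps=10.0)
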