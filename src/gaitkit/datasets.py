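"""Convenience constructors for labelled synthetic representation sets.

These tie the walker generator and the representation stage together into
ready-to-train arrays, assigning sequences to synthetic subjects so that
train/test splits can be made subject-disjoint (the evaluation protocol
used throughout).
"""

from __future__ import annotations

import numpy as np

from . import gaitsim, represent
from .sequences import SilhouetteSequence


def synthetic_energy_images(n_per_class: int, seed: int = 0,
                            kind: str = "GEI",
                            n_subjects_per_class: int = 10,
                            frames_per_cycle: int = 16,
                            n_cycles: int = 2,
                            noise_fraction: float = 0.0,
                            scale_shift: float = 1.0):
    """Whole-sequence energy images for all five gait types.

    Each class contributes ``n_per_class`` sequences spread round-robin over
    ``n_subjects_per_class`` synthetic subjects; a subject's morphology
    (limb-length scale) is fixed across classes, so subject-disjoint splits
    carry real subject structure.  ``noise_fraction`` flips that fraction of
    silhouette pixels and ``scale_shift`` rescales limb lengths, emulating a
    noisier capture domain for cross-domain experiments.

    Returns ``(images, labels, subjects)``: a (n, 224, 224) float32 array,
    a list of gait-type labels and a list of subject ids.
    """
    rng = np.random.default_rng(seed)
    images, labels, subjects = [], [], []
    for cls in gaitsim.GAIT_TYPES:
        for i in range(n_per_class):
            subj = i % n_subjects_per_class
            subj_scale = (0.88 + 0.24 * (subj / max(1, n_subjects_per_class - 1)))
            subj_scale *= scale_shift
            limbs = {k: v * subj_scale for k, v in
                     gaitsim._DEFAULT_LIMBS.items()}
            severity = 1 if cls == "normal" else 1 + (i % 2)
            direction = gaitsim.DIRECTIONS[(i // 2) % 2]
            cfg = gaitsim.WalkerConfig(
                gait_type=cls, severity=severity, direction=direction,
                frames_per_cycle=frames_per_cycle, n_cycles=n_cycles,
                limb_lengths=limbs,
                seed=int(rng.integers(0, 2 ** 31)),
            )
            seq = gaitsim.generate_walker_sequence(cfg, render_rgb=False)
            if kind == "GEI":
                source = SilhouetteSequence(seq.truth_masks, fps=10.0)
            else:
                source = seq.poses
            source = represent.canonicalize_direction(source, cfg.direction)
            if noise_fraction > 0 and kind == "GEI":
                masks = source.masks.copy()
                flip = rng.random(masks.shape) < noise_fraction
                masks ^= flip
                source = SilhouetteSequence(masks, fps=10.0)
            reps = represent.sequence_representations(source, kind=kind)
            images.append(reps[0].pixels)
            labels.append(cls)
            subjects.append(f"subj{subj:02d}")
    return np.stack(images), labels, subjects


def subject_split(subjects, test_subjects):
    """Boolean masks (train, test) for a subject-disjoint split."""
    subjects = np.asarray(subjects)
    test = np.isin(subjects, list(test_subjects))
    return ~test, test
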