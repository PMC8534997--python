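"""Core sequence containers shared across the pipeline.

A gait sequence travels through the pipeline in two parallel forms: a
:class:`SilhouetteSequence` of binary foreground masks (the substrate for
gait-cycle detection and the GEI) and a :class:`PoseSequence` of 25-keypoint
body poses (the substrate for skeleton rasterization and the SEI).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import body25


@dataclass
class SilhouetteSequence:
    """Ordered binary foreground masks with framerate metadata."""

    masks: np.ndarray  # (n_frames, H, W) bool
    fps: float = 10.0

    def __post_init__(self):
        self.masks = np.asarray(self.masks, dtype=bool)
        if self.masks.ndim != 3:
            raise ValueError("masks must be a (n_frames, H, W) array")
        if self.fps <= 0:
            raise ValueError("framerate must be positive")

    def __len__(self):
        return self.masks.shape[0]

    @property
    def frame_shape(self):
        return self.masks.shape[1:]


@dataclass
class PoseSequence:
    """Per-frame 25-keypoint body poses (x, y, confidence) in image coordinates."""

    keypoints: np.ndarray  # (n_frames, 25, 3) float
    frame_shape: tuple = (0, 0)  # (H, W)
    fps: float = 10.0

    def __post_init__(self):
        self.keypoints = np.asarray(self.keypoints, dtype=np.float32)
        if self.keypoints.ndim != 3 or self.keypoints.shape[1:] != (body25.N_KEYPOINTS, 3):
            raise ValueError("keypoints must be a (n_frames, 25, 3) array")
        conf = self.keypoints[:, :, 2]
        if conf.size and (conf.min() < 0 or conf.max() > 1):
            raise ValueError("confidences must lie in [0, 1]")
        if self.fps <= 0:
            raise ValueError("framerate must be positive")

    def __len__(self):
        return self.keypoints.shape[0]
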