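"""Gait representations: normalized silhouettes, gait cycles, GEI and SEI.

The gait energy image (GEI) averages the cropped, height-normalized and
horizontally aligned binary silhouettes of one gait cycle (or of a whole
sequence):

    E(x, y) = (1/N) * sum_i B_i(x, y)

where N is the number of frames averaged and B_i is the i-th normalized
binary image.  The skeleton energy image (SEI) is the same construction
applied to rasterized 25-keypoint skeleton frames instead of silhouettes;
both share the averaging code path by design.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as _dc_replace

import numpy as np
import scipy.ndimage as ndi
from scipy.signal import find_peaks
from skimage.draw import line as draw_line
from skimage.transform import resize

from . import body25
from .sequences import PoseSequence, SilhouetteSequence

#: side length of every gait representation, in pixels
REPRESENTATION_SIZE = 224

#: the effective framerate all representations are computed at
TARGET_FPS = 10.0

SKELETON_THICKNESS = 3       # px at capture resolution, before normalization
CONFIDENCE_THRESHOLD = 0.1   # keypoints at or below are treated as missing
_SMOOTH_WINDOW = 3           # moving-average window for the width signal


class EmptyMaskError(ValueError):
    """Raised when a silhouette frame has no foreground to normalize."""


@dataclass(frozen=True)
class GaitCycle:
    """Inclusive [start_frame, end_frame] indices of one gait cycle."""

    start_frame: int
    end_frame: int

    def __post_init__(self):
        if self.end_frame <= self.start_frame:
            raise ValueError("a cycle must span at least two frames")

    def __len__(self):
        return self.end_frame - self.start_frame + 1


@dataclass(frozen=True)
class GaitRepresentation:
    """A 224x224 grayscale energy image in [0, 1]."""

    pixels: np.ndarray
    kind: str                 # "GEI" | "SEI"
    scope: str                # "per_cycle" | "whole_sequence"
    cycle_index: int | None = None

    def __post_init__(self):
        px = np.asarray(self.pixels, dtype=np.float32)
        if px.shape != (REPRESENTATION_SIZE, REPRESENTATION_SIZE):
            raise ValueError(f"representation must be {REPRESENTATION_SIZE}x"
                             f"{REPRESENTATION_SIZE}, got {px.shape}")
        if px.min() < 0.0 or px.max() > 1.0:
            raise ValueError("intensities must lie in [0, 1]")
        if self.kind not in ("GEI", "SEI"):
            raise ValueError("kind must be 'GEI' or 'SEI'")
        if self.scope not in ("per_cycle", "whole_sequence"):
            raise ValueError("scope must be 'per_cycle' or 'whole_sequence'")
        object.__setattr__(self, "pixels", px)


# ---------------------------------------------------------------------------
# framerate and direction handling


def resample_framerate(sequence, target_fps: float = TARGET_FPS):
    """Uniformly subsample a sequence down to ``target_fps``.

    Frame k of the output is source frame round(k * src_fps / target_fps)
    (round half up).  Upsampling is refused.
    """
    if sequence.fps < target_fps:
        raise ValueError("cannot upsample: source framerate below target")
    if sequence.fps == target_fps:
        return sequence
    step = sequence.fps / target_fps
    n = len(sequence)
    idx = []
    k = 0
    while True:
        i = int(np.floor(k * step + 0.5))
        if i > n - 1:
            break
        idx.append(i)
        k += 1
    idx = np.asarray(idx, dtype=int)
    if isinstance(sequence, SilhouetteSequence):
        return SilhouetteSequence(masks=sequence.masks[idx], fps=target_fps)
    return PoseSequence(keypoints=sequence.keypoints[idx],
                        frame_shape=sequence.frame_shape, fps=target_fps)


def canonicalize_direction(sequence, direction: str):
    """Mirror right-to-left sequences so every sequence faces left-to-right.

    Masks are flipped horizontally; pose x-coordinates are reflected and
    left/right keypoint indices swapped.  Applying the operation twice is
    the identity.
    """
    if direction == "left_to_right":
        return sequence
    if direction != "right_to_left":
        raise ValueError(f"unknown direction {direction!r}")
    if isinstance(sequence, SilhouetteSequence):
        return SilhouetteSequence(masks=sequence.masks[:, :, ::-1].copy(),
                                  fps=sequence.fps)
    kps = sequence.keypoints.copy()
    width = sequence.frame_shape[1]
    used = kps[:, :, 2] > 0
    kps[:, :, 0][used] = (width - 1) - kps[:, :, 0][used]
    kps = np.stack([body25.swap_left_right(k) for k in kps])
    return PoseSequence(keypoints=kps, frame_shape=sequence.frame_shape,
                        fps=sequence.fps)


# ---------------------------------------------------------------------------
# silhouette normalization


def normalize_silhouette(mask) -> np.ndarray:
    """Crop, scale and align one binary silhouette onto the 224x224 canvas.

    The foreground bounding box is scaled so its height is 224 (aspect ratio
    preserved, width at least 1), re-binarized at 0.5, and placed with the
    silhouette's horizontal centroid at the central column; columns that
    overflow the canvas are clipped.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise EmptyMaskError("cannot normalize an empty silhouette")
    rows = np.where(mask.any(axis=1))[0]
    cols = np.where(mask.any(axis=0))[0]
    crop = mask[rows[0]:rows[-1] + 1, cols[0]:cols[-1] + 1]
    size = REPRESENTATION_SIZE
    scale = size / crop.shape[0]
    new_w = max(1, int(round(crop.shape[1] * scale)))
    scaled = resize(crop.astype(np.float32), (size, new_w), order=1,
                    anti_aliasing=False) > 0.5
    if not scaled.any():  # degenerate slivers can vanish at 0.5; keep a bar
        scaled = resize(crop.astype(np.float32), (size, new_w), order=0) > 0.0

    canvas = np.zeros((size, size), dtype=bool)
    centroid_col = ndi.center_of_mass(scaled)[1]
    offset = int(round(size / 2 - centroid_col))
    src_lo = max(0, -offset)
    src_hi = min(new_w, size - offset)
    if src_hi > src_lo:
        canvas[:, src_lo + offset:src_hi + offset] = scaled[:, src_lo:src_hi]
    return canvas


# ---------------------------------------------------------------------------
# gait-cycle detection


def bounding_box_width(sequence: SilhouetteSequence) -> np.ndarray:
    """Per-frame width of the silhouette bounding box (0 for empty frames)."""
    widths = np.zeros(len(sequence), dtype=float)
    for i, mask in enumerate(sequence.masks):
        cols = np.where(mask.any(axis=0))[0]
        if cols.size:
            widths[i] = cols[-1] - cols[0] + 1
    return widths


def detect_gait_cycles(sequence: SilhouetteSequence) -> list[GaitCycle]:
    """Delimit gait cycles from the silhouette bounding-box-width signal.

    The width of a walking silhouette reaches a local minimum twice per gait
    cycle (at each mid-stance, when the legs pass each other).  Minima of
    the moving-average-smoothed width signal are located and *alternate*
    minima delimit full cycles, since a cycle spans two strides.  Returns an
    empty list when no cycle can be found (e.g. a constant width signal).
    """
    widths = bounding_box_width(sequence)
    if len(widths) < 3 or np.ptp(widths) == 0:
        return []
    kernel = np.ones(_SMOOTH_WINDOW) / _SMOOTH_WINDOW
    smooth = np.convolve(widths, kernel, mode="same")
    prominence = 0.05 * np.ptp(smooth)
    minima, _ = find_peaks(-smooth, distance=2, prominence=prominence)
    if len(minima) < 3:
        return []
    cycles = []
    for a, b in zip(minima[:-2:2], minima[2::2]):
        cycles.append(GaitCycle(start_frame=int(a), end_frame=int(b)))
    return cycles


# ---------------------------------------------------------------------------
# skeleton rasterization


class AllLowConfidenceError(ValueError):
    """Raised when a pose frame has too few confident keypoints to draw."""


def rasterize_skeleton(pose_frame, frame_shape,
                       threshold: float = CONFIDENCE_THRESHOLD,
                       thickness: int = SKELETON_THICKNESS) -> np.ndarray:
    """Draw the BODY_25 limb segments of one pose frame as a binary image.

    A limb is drawn when both of its endpoint keypoints exceed the
    confidence threshold; segments are ``thickness`` pixels wide on the
    frame-sized canvas.
    """
    kp = np.asarray(pose_frame, dtype=np.float32)
    if kp.shape != (body25.N_KEYPOINTS, 3):
        raise ValueError("pose frame must be (25, 3)")
    ok = kp[:, 2] > threshold
    if ok.sum() < 2:
        raise AllLowConfidenceError("fewer than two confident keypoints")
    h, w = frame_shape
    canvas = np.zeros((h, w), dtype=bool)
    drawn = 0
    for a, b in body25.LIMB_PAIRS:
        if not (ok[a] and ok[b]):
            continue
        rr, cc = draw_line(int(round(kp[a, 1])), int(round(kp[a, 0])),
                           int(round(kp[b, 1])), int(round(kp[b, 0])))
        keep = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
        canvas[rr[keep], cc[keep]] = True
        drawn += 1
    if drawn and thickness > 1:
        canvas = ndi.binary_dilation(canvas, iterations=(thickness - 1) // 2 or 1)
    return canvas


def count_drawable_limbs(pose_frame, threshold: float = CONFIDENCE_THRESHOLD) -> int:
    """Number of BODY_25 limb pairs with both confidences above threshold."""
    kp = np.asarray(pose_frame)
    ok = kp[:, 2] > threshold
    return sum(1 for a, b in body25.LIMB_PAIRS if ok[a] and ok[b])


# ---------------------------------------------------------------------------
# energy images


def compute_energy_image(images, kind: str, scope: str,
                         cycle_index: int | None = None) -> GaitRepresentation:
    """Pixel-wise mean of normalized binary images: E = (1/N) sum_i B_i."""
    stack = np.asarray(list(images), dtype=np.float32)
    if stack.ndim != 3 or stack.shape[0] == 0:
        raise ValueError("need a nonempty stack of 2D images")
    if stack.shape[1:] != (REPRESENTATION_SIZE, REPRESENTATION_SIZE):
        raise ValueError("images must be normalized to 224x224 first")
    return GaitRepresentation(pixels=stack.mean(axis=0), kind=kind,
                              scope=scope, cycle_index=cycle_index)


def _normalized_frames(sequence, frame_range=None):
    """Normalized 224x224 binary frames; silhouettes or rasterized poses."""
    lo, hi = (0, len(sequence) - 1) if frame_range is None else frame_range
    out = []
    for i in range(lo, hi + 1):
        if isinstance(sequence, SilhouetteSequence):
            mask = sequence.masks[i]
        else:
            try:
                mask = rasterize_skeleton(sequence.keypoints[i],
                                          sequence.frame_shape)
            except AllLowConfidenceError:
                continue
        try:
            out.append(normalize_silhouette(mask))
        except EmptyMaskError:
            continue
    return out


def sequence_representations(sequence, kind: str,
                             cycles: list[GaitCycle] | None = None):
    """All representations of one canonicalized 10 fps sequence.

    Returns the whole-sequence representation followed by one per-cycle
    representation for each detected (or supplied) gait cycle.  ``kind``
    selects GEI (``sequence`` is a SilhouetteSequence) or SEI (the skeleton
    path of a PoseSequence); the averaging code path is shared.
    """
    reps = []
    frames = _normalized_frames(sequence)
    if not frames:
        raise EmptyMaskError("sequence contains no usable frames")
    reps.append(compute_energy_image(frames, kind=kind, scope="whole_sequence"))
    if cycles:
        for ci, cyc in enumerate(cycles):
            sub = _normalized_frames(sequence, (cyc.start_frame, cyc.end_frame))
            if sub:
                reps.append(compute_energy_image(sub, kind=kind,
                                                 scope="per_cycle",
                                                 cycle_index=ci))
    return reps
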