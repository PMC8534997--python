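"""Chroma-key silhouette extraction.

A background-only frame is converted to HSV and per-channel valid intervals
are learned from the channel histograms ([1st, 99th] percentile, with the
hue handled circularly).  Pixels of walking-subject frames whose HSV values
fall outside the background range are classified as foreground; a
morphological opening-then-closing removes speckle noise and the largest
connected component is kept as the silhouette.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi
from skimage.color import rgb2hsv
from skimage.morphology import closing, disk, opening

from .sequences import SilhouetteSequence

_PCT_LOW, _PCT_HIGH = 0.5, 99.5
_FOOTPRINT = disk(2)  # 5x5 elliptical structuring element


@dataclass(frozen=True)
class BackgroundModel:
    """Learned per-channel HSV intervals of the chroma background.

    The hue channel is circular, so its interval is stored together with the
    rotation ``hue_shift`` that centres the background hue mass at 0.5; a
    pixel's hue is tested after applying the same rotation.
    """

    hue_low: float
    hue_high: float
    hue_shift: float
    sat_low: float
    sat_high: float
    val_low: float
    val_high: float

    def contains(self, hsv):
        """Boolean mask of pixels inside all three background intervals."""
        h = (hsv[..., 0] + self.hue_shift) % 1.0
        in_h = (h >= self.hue_low) & (h <= self.hue_high)
        in_s = (hsv[..., 1] >= self.sat_low) & (hsv[..., 1] <= self.sat_high)
        in_v = (hsv[..., 2] >= self.val_low) & (hsv[..., 2] <= self.val_high)
        return in_h & in_s & in_v

    def foreground(self, hsv):
        """Pixels classified as the walking subject.

        Hue is the discriminative channel over a chroma background, so a
        pixel is foreground when its hue leaves the background interval, or
        when both saturation and value do (guarding against desaturated
        clothing whose hue is unreliable).
        """
        h = (hsv[..., 0] + self.hue_shift) % 1.0
        out_h = (h < self.hue_low) | (h > self.hue_high)
        out_s = (hsv[..., 1] < self.sat_low) | (hsv[..., 1] > self.sat_high)
        out_v = (hsv[..., 2] < self.val_low) | (hsv[..., 2] > self.val_high)
        return out_h | (out_s & out_v)

    def widened(self, margin):
        """Model with every interval enlarged by ``margin`` on both sides."""
        return BackgroundModel(
            hue_low=max(0.0, self.hue_low - margin),
            hue_high=min(1.0, self.hue_high + margin),
            hue_shift=self.hue_shift,
            sat_low=max(0.0, self.sat_low - margin),
            sat_high=min(1.0, self.sat_high + margin),
            val_low=max(0.0, self.val_low - margin),
            val_high=min(1.0, self.val_high + margin),
        )


def _as_hsv(frame):
    frame = np.asarray(frame)
    if frame.ndim != 3 or frame.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) RGB frame")
    if frame.dtype == np.uint8:
        frame = frame.astype(np.float64) / 255.0
    return rgb2hsv(frame)


def fit_background(background_frame) -> BackgroundModel:
    """Learn the HSV background intervals from a background-only frame.

    Intervals cover the [0.5th, 99.5th] percentile of each channel's
    histogram, so that (for unimodal noise) at least 99% of background
    pixels are accepted by the background test.
    The hue distribution is rotated so its circular mean sits at 0.5 before
    taking percentiles, which keeps a hue cluster straddling 0/1 intact.  A
    multimodal background (e.g. two differently coloured halves) is covered
    by one interval spanning both modes — silhouette quality is then the
    caller's responsibility.
    """
    hsv = _as_hsv(background_frame)
    if hsv.size == 0:
        raise ValueError("empty background frame")
    if float(np.ptp(hsv[..., 2])) == 0.0 and float(hsv[..., 2].max()) == 0.0:
        raise ValueError("degenerate background frame (all-black)")

    hue = hsv[..., 0].ravel()
    ang = hue * 2 * np.pi
    mean_ang = np.arctan2(np.sin(ang).mean(), np.cos(ang).mean())
    hue_shift = (0.5 - mean_ang / (2 * np.pi)) % 1.0
    hue_c = (hue + hue_shift) % 1.0

    lo = lambda x: float(np.percentile(x, _PCT_LOW))
    hi = lambda x: float(np.percentile(x, _PCT_HIGH))
    return BackgroundModel(
        hue_low=lo(hue_c), hue_high=hi(hue_c), hue_shift=hue_shift,
        sat_low=lo(hsv[..., 1]), sat_high=hi(hsv[..., 1]),
        val_low=lo(hsv[..., 2]), val_high=hi(hsv[..., 2]),
    )


def clean_mask(mask):
    """Morphological opening then closing with a 5x5 elliptical footprint."""
    return closing(opening(mask, _FOOTPRINT), _FOOTPRINT)


def largest_component(mask):
    """Keep only the largest connected foreground component (empty allowed)."""
    labels, n = ndi.label(mask)
    if n == 0:
        return np.zeros_like(mask, dtype=bool)
    sizes = ndi.sum_labels(mask, labels, index=np.arange(1, n + 1))
    return labels == (int(np.argmax(sizes)) + 1)


def extract_silhouette(frame, model: BackgroundModel, clean: bool = True):
    """Binary silhouette of one frame under a learned background model."""
    hsv = _as_hsv(frame)
    mask = model.foreground(hsv)
    if clean:
        mask = clean_mask(mask)
    return largest_component(mask)


def extract_sequence(frames, model: BackgroundModel, fps: float = 10.0) -> SilhouetteSequence:
    """Extract silhouettes for an ordered stack of equally sized frames."""
    frames = np.asarray(frames)
    masks = np.stack([extract_silhouette(f, model) for f in frames])
    return SilhouetteSequence(masks=masks, fps=fps)
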