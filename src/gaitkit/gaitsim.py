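"""Synthetic articulated-walker generator.

Procedurally renders labelled gait sequences — chroma-background RGB frames,
ground-truth silhouette masks and BODY_25 pose tracks — for five gait types
(normal, scissor, spastic, steppage, propulsive) at two severity levels, so
the full segmentation → representation → classification pipeline can be
built and tested without any recorded video.

The walker is a 2D sagittal stick figure with 13 articulated joints mapped
onto the BODY_25 index set (facial and foot indices are emitted with
confidence 0).  Joint-angle trajectories follow a sinusoidal base gait; each
pathological type perturbs that base:

* scissor   - forward-leaning torso, shortened steps, both feet swept in a
              circular dragging motion;
* spastic   - circular sweep of one (right) leg only, with the right arm
              held still at the waist (severity 1) or flexed against the
              chest (severity 2);
* steppage  - knee-flexion amplitude multiplied, lifting the knees high;
* propulsive- stooped torso, halved step length at doubled cadence, both
              arms held to the chest, plus additive body jitter.

Severity 2 scales a type's deviation parameters by ``SEVERITY2_SCALE``.
Sequence layout follows a studio capture protocol: per recording session,
4 sequences (2 directions x 2 repetitions) for each of 9 (type, severity)
conditions, i.e. 36 sequences per session and 828 for 23 sessions.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from skimage.draw import line as draw_line
from skimage.draw import ellipse as draw_ellipse
from skimage.morphology import disk

from . import body25
from .sequences import PoseSequence

GAIT_TYPES = ("scissor", "spastic", "steppage", "normal", "propulsive")
PATHOLOGICAL_TYPES = ("scissor", "spastic", "steppage", "propulsive")
DIRECTIONS = ("left_to_right", "right_to_left")

#: multiplier applied to a gait type's deviation parameters at severity 2
SEVERITY2_SCALE = 1.6

#: HSV band (low, high per channel) guaranteed to contain every background
#: pixel the generator emits (hue about one third of the hue circle = green).
BACKGROUND_HSV_BAND = {
    "hue": (0.31, 0.38),
    "saturation": (0.72, 0.90),
    "value": (0.68, 0.81),
}

_BACKGROUND_RGB = np.array([35, 190, 45], dtype=np.int16)
_BACKGROUND_NOISE = 8  # uniform +/- per channel
_PERSON_RGB = np.array([95, 85, 150], dtype=np.int16)
_PERSON_NOISE = 5

_DEFAULT_LIMBS = {
    "torso": 50.0,      # mid-hip to neck
    "head": 14.0,       # neck to head centre
    "upper_arm": 27.0,
    "lower_arm": 25.0,
    "thigh": 40.0,
    "shank": 38.0,
    "foot": 14.0,
}


@dataclass(frozen=True)
class WalkerConfig:
    """Full parameterization of one synthetic gait sequence."""

    gait_type: str = "normal"
    severity: int = 1
    frames_per_cycle: int = 20
    n_cycles: int = 2
    direction: str = "left_to_right"
    frame_height: int = 240
    frame_width: int | None = None  # None: sized so the walk fits with margins
    limb_lengths: dict = field(default_factory=lambda: dict(_DEFAULT_LIMBS))
    jitter_amplitude: float = 1.5
    seed: int = 0

    def __post_init__(self):
        if self.gait_type not in GAIT_TYPES:
            raise ValueError(f"unknown gait type {self.gait_type!r}")
        if self.severity not in (1, 2):
            raise ValueError("severity must be 1 or 2")
        if self.gait_type == "normal" and self.severity != 1:
            raise ValueError("normal gait has a single severity level (1)")
        if self.frames_per_cycle < 8:
            raise ValueError("frames_per_cycle must be >= 8")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be positive")
        if self.direction not in DIRECTIONS:
            raise ValueError(f"unknown direction {self.direction!r}")
        if any(v <= 0 for v in self.limb_lengths.values()):
            raise ValueError("all limb lengths must be positive")

    @property
    def n_frames(self):
        return self.frames_per_cycle * self.n_cycles


@dataclass
class SyntheticSequence:
    """Output of the generator: frames, truth masks and aligned poses."""

    frames: np.ndarray | None  # (n, H, W, 3) uint8, None if RGB skipped
    truth_masks: np.ndarray    # (n, H, W) bool
    poses: PoseSequence
    config: WalkerConfig

    def __len__(self):
        return self.truth_masks.shape[0]


# ---------------------------------------------------------------------------
# kinematics


def _gait_parameters(config: WalkerConfig):
    """Resolve a config into the numeric gait parameters of the walker."""
    f = SEVERITY2_SCALE if config.severity == 2 else 1.0
    p = {
        "hip_amp": 0.5,        # rad, thigh swing about vertical
        "knee_amp": 0.7,       # rad, peak swing-phase knee flexion
        "arm_amp": 0.5,        # rad
        "elbow_flex": 0.35,    # rad, constant
        "torso_pitch": 0.0,    # rad, forward lean
        "step_scale": 1.0,     # multiplies hip_amp (step length)
        "cadence": 1.0,        # step cycles per nominal gait cycle
        "circ_left": 0.0,      # px, circular foot-drag sweep amplitude
        "circ_right": 0.0,
        "left_arm": "swing",   # swing | waist | chest
        "right_arm": "swing",
        "jitter": 0.0,         # px, additive joint jitter (std)
    }
    g = config.gait_type
    if g == "scissor":
        p["torso_pitch"] = 0.30 * f
        p["step_scale"] = max(0.15, 1.0 - 0.40 * f)
        p["circ_left"] = p["circ_right"] = 5.0 * f
    elif g == "spastic":
        p["circ_right"] = 6.0 * f
        p["right_arm"] = "chest" if config.severity == 2 else "waist"
    elif g == "steppage":
        p["knee_amp"] *= 1.0 + 0.8 * f
    elif g == "propulsive":
        p["torso_pitch"] = 0.45 * f
        p["step_scale"] = max(0.10, 1.0 - 0.50 * f)
        p["cadence"] = 2.0
        p["left_arm"] = p["right_arm"] = "chest"
        p["jitter"] = config.jitter_amplitude * f
    return p


def _walker_keypoints(config: WalkerConfig, params, rng):
    """Joint trajectories for a left-to-right walk.

    Returns (keypoints (n, 25, 3), speed px/frame, x_extent).
    """
    L = config.limb_lengths
    n = config.n_frames
    T = config.frames_per_cycle
    hip_amp = params["hip_amp"] * params["step_scale"]
    step_len = 2.0 * L["thigh"] * np.sin(hip_amp)
    speed = 2.0 * step_len * params["cadence"] / T  # two steps per cycle
    hip_y0 = config.frame_height - 14 - (L["thigh"] + L["shank"])

    kps = np.zeros((n, body25.N_KEYPOINTS, 3), dtype=np.float32)
    for t in range(n):
        phi = 2.0 * np.pi * params["cadence"] * t / T
        mid_hip = np.array([0.0, hip_y0 + 2.0 * np.cos(2.0 * phi)])
        pitch = params["torso_pitch"]
        up = np.array([np.sin(pitch), -np.cos(pitch)])  # forward lean is +x
        neck = mid_hip + L["torso"] * up
        head = neck + L["head"] * up
        nose = head + np.array([7.0, 0.0])

        pts = {body25.MID_HIP: mid_hip, body25.NECK: neck, body25.NOSE: nose}

        for side, sign, circ, arm_mode in (
            ("l", 1.0, params["circ_left"], params["left_arm"]),
            ("r", -1.0, params["circ_right"], params["right_arm"]),
        ):
            ph = phi if side == "l" else phi + np.pi
            # leg
            hip = mid_hip + np.array([2.0 * sign, 2.0])
            th = hip_amp * np.sin(ph)
            knee_flex = params["knee_amp"] * 0.5 * (1.0 + np.sin(ph + 1.2))
            knee = hip + L["thigh"] * np.array([np.sin(th), np.cos(th)])
            sh = th - knee_flex
            ankle = knee + L["shank"] * np.array([np.sin(sh), np.cos(sh)])
            if circ > 0.0:
                ankle = ankle + np.array([circ * np.cos(ph),
                                          -0.6 * circ * max(0.0, np.sin(ph))])
            # arm
            shoulder = neck + np.array([2.0 * sign, 2.0])
            if arm_mode == "swing":
                ta = params["arm_amp"] * np.sin(ph + np.pi)
                elbow = shoulder + L["upper_arm"] * np.array([np.sin(ta), np.cos(ta)])
                tw = ta - params["elbow_flex"]
                wrist = elbow + L["lower_arm"] * np.array([np.sin(tw), np.cos(tw)])
            elif arm_mode == "waist":
                elbow = shoulder + L["upper_arm"] * np.array([0.15, 0.98])
                wrist = mid_hip + np.array([2.0 * sign + 5.0, 0.0])
            else:  # chest
                chest = neck + 0.35 * (mid_hip - neck) + np.array([8.0, 0.0])
                elbow = shoulder + L["upper_arm"] * np.array([0.55, 0.80])
                wrist = chest
            idx = {
                "l": (body25.L_HIP, body25.L_KNEE, body25.L_ANKLE,
                      body25.L_SHOULDER, body25.L_ELBOW, body25.L_WRIST),
                "r": (body25.R_HIP, body25.R_KNEE, body25.R_ANKLE,
                      body25.R_SHOULDER, body25.R_ELBOW, body25.R_WRIST),
            }[side]
            for i, pt in zip(idx, (hip, knee, ankle, shoulder, elbow, wrist)):
                pts[i] = pt

        for i, pt in pts.items():
            kps[t, i, 0] = pt[0] + speed * t
            kps[t, i, 1] = pt[1]
            kps[t, i, 2] = 0.95
        if params["jitter"] > 0.0:
            used = kps[t, :, 2] > 0
            kps[t, used, :2] += rng.normal(0.0, params["jitter"],
                                           size=(used.sum(), 2)).astype(np.float32)
    return kps, speed


# ---------------------------------------------------------------------------
# rendering


def _render_mask(kps_frame, config: WalkerConfig, width, _structure=None):
    """Rasterize one pose into a silhouette sprite (the ground-truth mask)."""
    L = config.limb_lengths
    h, w = config.frame_height, width
    canvas = np.zeros((h, w), dtype=bool)
    kp = kps_frame

    def seg(a, b):
        r0, c0 = int(round(kp[a, 1])), int(round(kp[a, 0]))
        r1, c1 = int(round(kp[b, 1])), int(round(kp[b, 0]))
        rr, cc = draw_line(r0, c0, r1, c1)
        ok = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
        canvas[rr[ok], cc[ok]] = True

    for a, b in [
        (body25.MID_HIP, body25.NECK),
        (body25.NECK, body25.L_SHOULDER), (body25.L_SHOULDER, body25.L_ELBOW),
        (body25.L_ELBOW, body25.L_WRIST),
        (body25.NECK, body25.R_SHOULDER), (body25.R_SHOULDER, body25.R_ELBOW),
        (body25.R_ELBOW, body25.R_WRIST),
        (body25.MID_HIP, body25.L_HIP), (body25.L_HIP, body25.L_KNEE),
        (body25.L_KNEE, body25.L_ANKLE),
        (body25.MID_HIP, body25.R_HIP), (body25.R_HIP, body25.R_KNEE),
        (body25.R_KNEE, body25.R_ANKLE),
        (body25.NECK, body25.NOSE),
    ]:
        seg(a, b)

    # feet: short forward segments from the ankles (toe keypoints unused)
    for ankle in (body25.L_ANKLE, body25.R_ANKLE):
        r0, c0 = int(round(kp[ankle, 1])), int(round(kp[ankle, 0]))
        r1, c1 = r0 + 3, c0 + int(round(L["foot"]))
        rr, cc = draw_line(r0, c0, r1, c1)
        ok = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
        canvas[rr[ok], cc[ok]] = True

    if _structure is None:
        figure_h = L["torso"] + L["thigh"] + L["shank"] + 2 * L["head"]
        thickness = max(2, int(round(0.06 * figure_h / 2)))  # limb half-width
        _structure = disk(thickness).astype(bool)
    canvas = ndi.binary_dilation(canvas, structure=_structure)

    # head: filled ellipse above the neck
    head_c = kp[body25.NECK, :2] + (L["head"] + 4) * _unit(
        kp[body25.NECK, :2], kp[body25.MID_HIP, :2])
    rr, cc = draw_ellipse(head_c[1], head_c[0], L["head"] * 0.8, L["head"] * 0.62,
                          shape=(h, w))
    canvas[rr, cc] = True
    # torso bulk
    mid = 0.5 * (kp[body25.NECK, :2] + kp[body25.MID_HIP, :2])
    d = kp[body25.NECK, :2] - kp[body25.MID_HIP, :2]
    rot = np.arctan2(d[0], -d[1])
    rr, cc = draw_ellipse(mid[1], mid[0], L["torso"] * 0.55, 10.0,
                          rotation=rot, shape=(h, w))
    canvas[rr, cc] = True
    return canvas


def _unit(a, b):
    """Unit vector from b through a, extended (head sits past the neck)."""
    v = a - b
    n = np.linalg.norm(v)
    return v / n if n > 0 else np.array([0.0, -1.0])


def _compose_rgb(mask, rng):
    h, w = mask.shape
    noise = rng.integers(-_BACKGROUND_NOISE, _BACKGROUND_NOISE + 1,
                         size=(h, w, 3), dtype=np.int16)
    frame = _BACKGROUND_RGB + noise
    frame[mask] = _PERSON_RGB + np.clip(noise[mask], -_PERSON_NOISE, _PERSON_NOISE)
    return np.clip(frame, 0, 255).astype(np.uint8)


def background_frame(height=240, width=320, seed=0):
    """A background-only chroma frame, as captured before the subject enters."""
    rng = np.random.default_rng(seed)
    h, w = height, width
    frame = _BACKGROUND_RGB + rng.integers(-_BACKGROUND_NOISE, _BACKGROUND_NOISE + 1,
                                           size=(h, w, 3), dtype=np.int16)
    return np.clip(frame, 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# public operations


def generate_walker_sequence(config: WalkerConfig, render_rgb: bool = True) -> SyntheticSequence:
    """Generate one labelled synthetic gait sequence.

    Identical configs (including ``seed``) produce bit-identical output.
    When ``render_rgb`` is false only truth masks and poses are produced,
    which is all the representation stages need.
    """
    rng = np.random.default_rng(config.seed)
    params = _gait_parameters(config)
    kps, speed = _walker_keypoints(config, params, rng)

    used = kps[:, :, 2] > 0
    x_min = kps[:, :, 0][used].min()
    x_max = kps[:, :, 0][used].max()
    margin = 36.0
    kps[:, :, 0][used] += margin - x_min
    width = config.frame_width
    if width is None:
        width = int(np.ceil(x_max - x_min + 2 * margin))

    n = config.n_frames
    L = config.limb_lengths
    figure_h = L["torso"] + L["thigh"] + L["shank"] + 2 * L["head"]
    structure = disk(max(2, int(round(0.06 * figure_h / 2)))).astype(bool)
    masks = np.zeros((n, config.frame_height, width), dtype=bool)
    for t in range(n):
        masks[t] = _render_mask(kps[t], config, width, _structure=structure)

    frames = None
    if render_rgb:
        frames = np.empty((n, config.frame_height, width, 3), dtype=np.uint8)
        for t in range(n):
            frames[t] = _compose_rgb(masks[t], rng)

    if config.direction == "right_to_left":
        masks = masks[:, :, ::-1].copy()
        if frames is not None:
            frames = frames[:, :, ::-1].copy()
        kps[:, :, 0][used] = (width - 1) - kps[:, :, 0][used]
        kps = np.stack([body25.swap_left_right(kps[t]) for t in range(n)])

    poses = PoseSequence(kps, frame_shape=(config.frame_height, width), fps=10.0)
    return SyntheticSequence(frames=frames, truth_masks=masks, poses=poses,
                             config=config)


def session_conditions():
    """The 9 (gait_type, severity) conditions recorded in every session."""
    conds = [("normal", 1)]
    for t in PATHOLOGICAL_TYPES:
        conds.extend([(t, 1), (t, 2)])
    return conds


def generate_manifest(n_sessions: int, seed: int = 0, n_subjects: int | None = None) -> pd.DataFrame:
    """Manifest of a studio-protocol dataset: 36 sequences per session.

    Each session records 4 sequences (2 directions x 2 repetitions) for each
    of the 9 conditions.  23 sessions therefore yield 828 sequences.  Subjects
    are assigned so every session maps to one subject; when ``n_sessions``
    exceeds the subject pool (default ``min(n_sessions, 21)``), extra sessions
    reuse randomly chosen subjects, emulating capture on two different days.
    """
    if n_sessions < 1:
        raise ValueError("n_sessions must be >= 1")
    if n_subjects is None:
        n_subjects = min(n_sessions, 21)
    rng = np.random.default_rng(seed)
    subjects = [f"subj{j + 1:02d}" for j in range(n_subjects)]
    assignment = list(subjects)
    while len(assignment) < n_sessions:
        k = min(n_subjects, n_sessions - len(assignment))
        assignment.extend(rng.choice(subjects, size=k, replace=False))
    rows = []
    for s in range(n_sessions):
        session_id = f"sess{s + 1:02d}"
        for gait_type, severity in session_conditions():
            for direction in DIRECTIONS:
                for rep in (1, 2):
                    uri = f"{session_id}/{gait_type}_s{severity}_{direction}_r{rep}"
                    rows.append((session_id, assignment[s], gait_type, severity,
                                 direction, rep, uri))
    return pd.DataFrame(rows, columns=["session_id", "subject_id", "gait_type",
                                       "severity", "direction",
                                       "repetition_index", "sequence_uri"])


def config_for_row(row, base: WalkerConfig | None = None, seed: int = 0) -> WalkerConfig:
    """Per-sequence WalkerConfig for a manifest row.

    Subject identity perturbs limb lengths (a fixed per-subject morphology
    drawn from the subject id) and the row index sets the sequence seed, so
    repetitions differ only through their stochastic components.
    """
    base = base or WalkerConfig()
    subj_rng = np.random.default_rng(zlib.crc32(row.subject_id.encode()))
    scale = 0.9 + 0.2 * subj_rng.random()
    limbs = {k: v * scale for k, v in base.limb_lengths.items()}
    row_seed = (seed * 100003 + zlib.crc32(row.sequence_uri.encode())) % (2 ** 31)
    return replace(base, gait_type=row.gait_type, severity=int(row.severity),
                   direction=row.direction, limb_lengths=limbs, seed=row_seed)
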