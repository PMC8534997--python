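"""File formats: frames, masks, poses, representations, manifests, reports.

Frames, masks and energy images are stored as numbered 8-bit PNG files;
poses use the OpenPose JSON output convention (one document per frame with
a ``people`` list whose entries hold a flat 75-number ``pose_keypoints_2d``
array); manifests are CSV with a header row.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from . import body25
from .represent import GaitRepresentation
from .sequences import PoseSequence, SilhouetteSequence


class EmptyPoseError(ValueError):
    """Raised when a pose document contains no people."""


# ---------------------------------------------------------------------------
# poses (OpenPose convention)


def write_pose_file(path, keypoints) -> None:
    """Write one frame's (25, 3) keypoints as an OpenPose-style document."""
    kp = np.asarray(keypoints, dtype=float)
    if kp.shape != (body25.N_KEYPOINTS, 3):
        raise ValueError("keypoints must be (25, 3)")
    doc = {"version": 1.3,
           "people": [{"person_id": [-1],
                       "pose_keypoints_2d": [round(float(v), 3)
                                             for v in kp.ravel()]}]}
    Path(path).write_text(json.dumps(doc))


def read_pose_file(path) -> np.ndarray:
    """Parse one pose document into a (25, 3) array.

    With several detected people the one with the highest total confidence
    is taken (sequences film a single subject; extra detections are noise).
    Zero-confidence triplets are preserved.  An empty ``people`` list raises
    :class:`EmptyPoseError`; malformed documents raise ``ValueError``.
    """
    try:
        doc = json.loads(Path(path).read_text())
        people = doc["people"]
    except (json.JSONDecodeError, KeyError, TypeError) as e:
        raise ValueError(f"malformed pose document {path}: {e}") from None
    if not people:
        raise EmptyPoseError(f"no people in pose document {path}")
    best, best_conf = None, -1.0
    for person in people:
        flat = np.asarray(person["pose_keypoints_2d"], dtype=np.float32)
        if flat.shape != (body25.N_KEYPOINTS * 3,):
            raise ValueError(f"pose array must hold 75 numbers, got {flat.size}")
        kp = flat.reshape(body25.N_KEYPOINTS, 3)
        conf = float(kp[:, 2].sum())
        if conf > best_conf:
            best, best_conf = kp, conf
    return best


def write_pose_sequence(directory, poses: PoseSequence, stem="frame") -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i, kp in enumerate(poses.keypoints):
        write_pose_file(directory / f"{stem}_{i:04d}_keypoints.json", kp)


def read_pose_sequence(directory, frame_shape, fps=10.0) -> PoseSequence:
    files = sorted(Path(directory).glob("*_keypoints.json"))
    if not files:
        raise FileNotFoundError(f"no pose documents in {directory}")
    kps = np.stack([read_pose_file(f) for f in files])
    return PoseSequence(keypoints=kps, frame_shape=tuple(frame_shape), fps=fps)


# ---------------------------------------------------------------------------
# images


def write_image(path, array) -> None:
    """Write an 8-bit PNG; boolean masks map to {0, 255}, floats to 0..255."""
    arr = np.asarray(array)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8) * 255
    elif np.issubdtype(arr.dtype, np.floating):
        arr = np.round(np.clip(arr, 0, 1) * 255).astype(np.uint8)
    iio.imwrite(Path(path), arr)


def read_mask(path) -> np.ndarray:
    return np.asarray(iio.imread(Path(path))) > 127


def read_frame(path) -> np.ndarray:
    return np.asarray(iio.imread(Path(path)))


def write_frame_sequence(directory, arrays, stem="frame") -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i, arr in enumerate(arrays):
        write_image(directory / f"{stem}_{i:04d}.png", arr)


def read_mask_sequence(directory, fps=10.0) -> SilhouetteSequence:
    files = sorted(Path(directory).glob("*.png"))
    if not files:
        raise FileNotFoundError(f"no mask images in {directory}")
    return SilhouetteSequence(np.stack([read_mask(f) for f in files]), fps=fps)


# ---------------------------------------------------------------------------
# representations


def representation_filename(sequence_id, kind, scope, cycle_index=None) -> str:
    name = f"{sequence_id}_{kind}_{scope}"
    if cycle_index is not None:
        name += f"_{cycle_index}"
    return name + ".png"


def write_representation(path, rep: GaitRepresentation) -> None:
    write_image(path, rep.pixels)


def read_representation(path, kind=None, scope="whole_sequence") -> GaitRepresentation:
    arr = np.asarray(iio.imread(Path(path))).astype(np.float32) / 255.0
    kind = kind or ("SEI" if "_SEI_" in Path(path).name else "GEI")
    return GaitRepresentation(pixels=arr, kind=kind, scope=scope)


# ---------------------------------------------------------------------------
# manifests


def write_manifest(path, manifest: pd.DataFrame) -> None:
    manifest.to_csv(Path(path), index=False)


def read_manifest(path) -> pd.DataFrame:
    return pd.read_csv(Path(path))
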