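"""Constants for the OpenPose BODY_25 keypoint convention.

The pose-estimation tool the pipeline consumes emits 25 body keypoints per
person as a flat array of (x, y, confidence) triplets.  This module is the
single source of truth for keypoint indices, the limb pairs used to draw
skeleton images, and the left/right index swap applied when a sequence is
mirrored horizontally.
"""

N_KEYPOINTS = 25

NOSE = 0
NECK = 1
R_SHOULDER, R_ELBOW, R_WRIST = 2, 3, 4
L_SHOULDER, L_ELBOW, L_WRIST = 5, 6, 7
MID_HIP = 8
R_HIP, R_KNEE, R_ANKLE = 9, 10, 11
L_HIP, L_KNEE, L_ANKLE = 12, 13, 14
R_EYE, L_EYE = 15, 16
R_EAR, L_EAR = 17, 18
L_BIG_TOE, L_SMALL_TOE, L_HEEL = 19, 20, 21
R_BIG_TOE, R_SMALL_TOE, R_HEEL = 22, 23, 24

KEYPOINT_NAMES = [
    "nose", "neck",
    "r_shoulder", "r_elbow", "r_wrist",
    "l_shoulder", "l_elbow", "l_wrist",
    "mid_hip",
    "r_hip", "r_knee", "r_ankle",
    "l_hip", "l_knee", "l_ankle",
    "r_eye", "l_eye", "r_ear", "l_ear",
    "l_big_toe", "l_small_toe", "l_heel",
    "r_big_toe", "r_small_toe", "r_heel",
]

# Standard BODY_25 limb connectivity (the pair list the pose tool renders).
LIMB_PAIRS = [
    (NECK, MID_HIP),
    (NECK, R_SHOULDER), (R_SHOULDER, R_ELBOW), (R_ELBOW, R_WRIST),
    (NECK, L_SHOULDER), (L_SHOULDER, L_ELBOW), (L_ELBOW, L_WRIST),
    (MID_HIP, R_HIP), (R_HIP, R_KNEE), (R_KNEE, R_ANKLE),
    (MID_HIP, L_HIP), (L_HIP, L_KNEE), (L_KNEE, L_ANKLE),
    (NECK, NOSE),
    (NOSE, R_EYE), (R_EYE, R_EAR),
    (NOSE, L_EYE), (L_EYE, L_EAR),
    (L_ANKLE, L_BIG_TOE), (L_BIG_TOE, L_SMALL_TOE), (L_ANKLE, L_HEEL),
    (R_ANKLE, R_BIG_TOE), (R_BIG_TOE, R_SMALL_TOE), (R_ANKLE, R_HEEL),
]

# index -> index mapping applied when a frame is mirrored left<->right
LEFT_RIGHT_SWAP = {
    R_SHOULDER: L_SHOULDER, L_SHOULDER: R_SHOULDER,
    R_ELBOW: L_ELBOW, L_ELBOW: R_ELBOW,
    R_WRIST: L_WRIST, L_WRIST: R_WRIST,
    R_HIP: L_HIP, L_HIP: R_HIP,
    R_KNEE: L_KNEE, L_KNEE: R_KNEE,
    R_ANKLE: L_ANKLE, L_ANKLE: R_ANKLE,
    R_EYE: L_EYE, L_EYE: R_EYE,
    R_EAR: L_EAR, L_EAR: R_EAR,
    R_BIG_TOE: L_BIG_TOE, L_BIG_TOE: R_BIG_TOE,
    R_SMALL_TOE: L_SMALL_TOE, L_SMALL_TOE: R_SMALL_TOE,
    R_HEEL: L_HEEL, L_HEEL: R_HEEL,
}


def swap_left_right(keypoints):
    """Return a copy of a (25, 3) keypoint array with left/right indices swapped."""
    out = keypoints.copy()
    for src, dst in LEFT_RIGHT_SWAP.items():
        out[dst] = keypoints[src]
    return out
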