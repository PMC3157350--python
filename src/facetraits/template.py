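"""The 21-point fiducial landmark template.

Every face in the pipeline is annotated with the same ordered set of 21
anatomical points (brows, eye corners, nose, mouth, chin and cheek/jaw
contour) in pixel coordinates: origin top-left, x rightward, y downward.
The ordering is fixed package-wide so that descriptor feature indices are
stable across faces and runs.
"""

from __future__ import annotations

import numpy as np

#: Ordered landmark names; index in this tuple == anatomical identity.
LANDMARK_NAMES: tuple[str, ...] = (
    "brow_l_outer",   # 0
    "brow_l_inner",   # 1
    "brow_r_inner",   # 2
    "brow_r_outer",   # 3
    "eye_l_outer",    # 4
    "eye_l_inner",    # 5
    "eye_r_inner",    # 6
    "eye_r_outer",    # 7
    "nose_bridge",    # 8
    "nose_tip",       # 9
    "nostril_l",      # 10
    "nostril_r",      # 11
    "mouth_l",        # 12
    "mouth_r",        # 13
    "lip_upper",      # 14
    "lip_lower",      # 15
    "chin",           # 16
    "jaw_l",          # 17
    "jaw_r",          # 18
    "cheek_l",        # 19
    "cheek_r",        # 20
)

N_POINTS: int = len(LANDMARK_NAMES)

LANDMARK_INDEX: dict[str, int] = {name: i for i, name in enumerate(LANDMARK_NAMES)}

# Template coordinates in a unit face box ([0,1] x [0,1], y downward).
# Chosen so a frontal neutral face fills the box with enough margin that
# sampled shape perturbations stay inside the image.
_UNIT_TEMPLATE = np.array(
    [
        (0.22, 0.33),  # brow_l_outer
        (0.38, 0.31),  # brow_l_inner
        (0.62, 0.31),  # brow_r_inner
        (0.78, 0.33),  # brow_r_outer
        (0.25, 0.40),  # eye_l_outer
        (0.38, 0.40),  # eye_l_inner
        (0.62, 0.40),  # eye_r_inner
        (0.75, 0.40),  # eye_r_outer
        (0.50, 0.42),  # nose_bridge
        (0.50, 0.58),  # nose_tip
        (0.43, 0.61),  # nostril_l
        (0.57, 0.61),  # nostril_r
        (0.36, 0.70),  # mouth_l
        (0.64, 0.70),  # mouth_r
        (0.50, 0.67),  # lip_upper
        (0.50, 0.74),  # lip_lower
        (0.50, 0.90),  # chin
        (0.27, 0.78),  # jaw_l
        (0.73, 0.78),  # jaw_r
        (0.17, 0.55),  # cheek_l
        (0.83, 0.55),  # cheek_r
    ],
    dtype=float,
)


def template_landmarks(image_size: tuple[int, int]) -> np.ndarray:
    """Scale the unit template into pixel coordinates for an (H, W) image.

    Returns an (21, 2) array of (x, y) pixel coordinates.
    """
    h, w = image_size
    pts = _UNIT_TEMPLATE.copy()
    pts[:, 0] *= w
    pts[:, 1] *= h
    return pts


def _dist(points: np.ndarray, a: str, b: str) -> float:
    return float(np.linalg.norm(points[LANDMARK_INDEX[a]] - points[LANDMARK_INDEX[b]]))


def structural_features(points: np.ndarray) -> dict[str, float]:
    """Named structural measurements of a landmark configuration.

    These are the interpretable quantities (inter-ocular distance, mouth
    width, ...) the synthetic generator can plant trait signal on, all in
    pixel units.
    """
    ix = LANDMARK_INDEX
    eye_l = 0.5 * (points[ix["eye_l_outer"]] + points[ix["eye_l_inner"]])
    eye_r = 0.5 * (points[ix["eye_r_outer"]] + points[ix["eye_r_inner"]])
    brow_l = 0.5 * (points[ix["brow_l_outer"]] + points[ix["brow_l_inner"]])
    brow_r = 0.5 * (points[ix["brow_r_outer"]] + points[ix["brow_r_inner"]])
    return {
        "inter_ocular_distance": float(np.linalg.norm(eye_l - eye_r)),
        "mouth_width": _dist(points, "mouth_l", "mouth_r"),
        "chin_mouth_distance": _dist(points, "lip_lower", "chin"),
        "face_width": _dist(points, "cheek_l", "cheek_r"),
        "jaw_width": _dist(points, "jaw_l", "jaw_r"),
        "eye_width": 0.5
        * (_dist(points, "eye_l_outer", "eye_l_inner") + _dist(points, "eye_r_outer", "eye_r_inner")),
        "brow_eye_distance": 0.5
        * float((eye_l[1] - brow_l[1]) + (eye_r[1] - brow_r[1])),
        "nose_length": _dist(points, "nose_bridge", "nose_tip"),
        "lip_thickness": _dist(points, "lip_upper", "lip_lower"),
        "face_height": _dist(points, "nose_bridge", "chin"),
    }


#: Per-face appearance parameters the renderer consumes; values in [0, 1].
APPEARANCE_PARAMS: tuple[str, ...] = ("skin_intensity", "brow_intensity", "lip_intensity")

STRUCTURAL_FEATURE_NAMES: tuple[str, ...] = (
    "inter_ocular_distance",
    "mouth_width",
    "chin_mouth_distance",
    "face_width",
    "jaw_width",
    "eye_width",
    "brow_eye_distance",
    "nose_length",
    "lip_thickness",
    "face_height",
)

KNOWN_TRAIT_FEATURES: tuple[str, ...] = STRUCTURAL_FEATURE_NAMES + APPEARANCE_PARAMS
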