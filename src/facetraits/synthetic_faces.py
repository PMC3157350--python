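"""Synthetic rated-face generator with planted trait signals.

Emulates, at desk scale, a database of randomly generated neutral frontal
faces: landmarks are drawn from a low-rank statistical shape model around
the 21-point template, a grayscale face is rendered deterministically from
the landmarks (plus a few per-face appearance parameters such as brow
darkness), and nine continuous trait scores on a 1–9 rating scale are
produced from *known* structural/appearance features plus additive
rater-like Gaussian noise.  Because the generating weights are known,
downstream recovery (classification accuracy, point-importance maps) can
be tested against planted ground truth.

Determinism contract: a fixed config seed yields a byte-identical dataset.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage import draw as skdraw

from .template import (
    APPEARANCE_PARAMS,
    KNOWN_TRAIT_FEATURES,
    LANDMARK_INDEX,
    N_POINTS,
    structural_features,
    template_landmarks,
)

__all__ = [
    "TRAITS",
    "TraitSpec",
    "SyntheticConfig",
    "FaceSample",
    "ConfigError",
    "build_shape_model",
    "render_face",
    "sample_face",
    "assign_trait_scores",
    "default_trait_specs",
    "planted_benchmark_specs",
    "generate_dataset",
]

#: The nine evaluated trait judgments, in the conventional table order.
TRAITS: tuple[str, ...] = (
    "attractive",
    "competent",
    "trustworthy",
    "dominant",
    "mean",
    "frightening",
    "extroverted",
    "threatening",
    "likable",
)

RATING_MIN, RATING_MAX = 1.0, 9.0

_RETRY_CAP = 10  # out-of-bounds landmark resamples per face


class ConfigError(ValueError):
    """Invalid generator configuration."""


@dataclass(frozen=True)
class TraitSpec:
    """Planted generating model for one trait score.

    score = clip(intercept + Σ w·feature + N(0, noise_sd²), 1, 9), where
    features are named structural measurements (pixel units) or appearance
    parameters (unit scale).
    """

    trait_name: str
    weights: dict[str, float]
    intercept: float = 5.0
    noise_sd: float = 0.5

    def validate(self) -> None:
        if not any(w != 0.0 for w in self.weights.values()):
            raise ConfigError(f"trait {self.trait_name!r}: needs at least one nonzero weight")
        unknown = sorted(set(self.weights) - set(KNOWN_TRAIT_FEATURES))
        if unknown:
            raise ConfigError(
                f"trait {self.trait_name!r}: unknown feature(s) {unknown}; "
                f"known features: {sorted(KNOWN_TRAIT_FEATURES)}"
            )
        if self.noise_sd < 0:
            raise ConfigError(f"trait {self.trait_name!r}: noise_sd must be >= 0")


@dataclass(frozen=True)
class SyntheticConfig:
    n_faces: int = 300
    n_points: int = N_POINTS
    shape_modes: int = 5
    mode_sd: float = 3.0
    image_size: tuple[int, int] = (64, 64)
    trait_specs: tuple[TraitSpec, ...] | None = None  # None -> default_trait_specs()
    rater_noise_sd: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_faces < 1:
            raise ConfigError("n_faces must be >= 1")
        if self.n_points != N_POINTS:
            raise ConfigError(f"n_points must match the {N_POINTS}-point template")
        if self.shape_modes < 0 or self.shape_modes > 2 * self.n_points:
            raise ConfigError("shape_modes must be in [0, 2 * n_points]")
        if self.mode_sd <= 0:
            raise ConfigError("mode_sd must be > 0")
        if self.image_size[0] <= 0 or self.image_size[1] <= 0:
            raise ConfigError("image dimensions must be positive")
        if self.rater_noise_sd < 0:
            raise ConfigError("rater_noise_sd must be >= 0")
        for spec in self.resolved_trait_specs():
            spec.validate()

    def resolved_trait_specs(self) -> tuple[TraitSpec, ...]:
        if self.trait_specs is not None:
            return tuple(self.trait_specs)
        return default_trait_specs(noise_sd=self.rater_noise_sd, image_size=self.image_size)


@dataclass
class FaceSample:
    """One face: rendered grayscale image, landmarks, and trait scores."""

    id: str
    image: np.ndarray  # (H, W) floats in [0, 1]
    landmarks: np.ndarray  # (P, 2) pixel (x, y)
    scores: dict[str, float] = field(default_factory=dict)
    appearance: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Shape model


def _structured_directions(template: np.ndarray) -> list[np.ndarray]:
    """Interpretable landmark-deformation directions (unnormalized).

    Ordered so that the leading shape modes correspond to face width/height,
    mouth width, inter-ocular spacing and brow height — the measurements the
    default trait specs plant signal on.
    """
    ix = LANDMARK_INDEX
    p = template.shape[0]
    center = template.mean(axis=0)
    dirs = []

    d = np.zeros((p, 2))
    d[:, 0] = template[:, 0] - center[0]  # width scaling
    dirs.append(d)

    d = np.zeros((p, 2))
    d[:, 1] = template[:, 1] - center[1]  # height scaling
    dirs.append(d)

    d = np.zeros((p, 2))  # mouth widening
    d[ix["mouth_l"], 0] = -1.0
    d[ix["mouth_r"], 0] = 1.0
    dirs.append(d)

    d = np.zeros((p, 2))  # inter-ocular spacing (eyes + brows)
    for name in (
        "brow_l_outer", "brow_l_inner", "brow_r_inner", "brow_r_outer",
        "eye_l_outer", "eye_l_inner", "eye_r_inner", "eye_r_outer",
    ):
        d[ix[name], 0] = np.sign(template[ix[name], 0] - center[0])
    dirs.append(d)

    d = np.zeros((p, 2))  # brow raise/lower
    for name in ("brow_l_outer", "brow_l_inner", "brow_r_inner", "brow_r_outer"):
        d[ix[name], 1] = -1.0
    dirs.append(d)

    d = np.zeros((p, 2))  # chin lengthening
    d[ix["chin"], 1] = 1.0
    d[ix["jaw_l"], 1] = 0.5
    d[ix["jaw_r"], 1] = 0.5
    dirs.append(d)

    d = np.zeros((p, 2))  # nose lengthening
    d[ix["nose_tip"], 1] = 1.0
    d[ix["nostril_l"], 1] = 1.0
    d[ix["nostril_r"], 1] = 1.0
    dirs.append(d)

    d = np.zeros((p, 2))  # lip thickening
    d[ix["lip_upper"], 1] = -0.5
    d[ix["lip_lower"], 1] = 0.5
    dirs.append(d)

    return [d.ravel() for d in dirs]


def build_shape_model(
    n_points: int,
    shape_modes: int,
    seed: int,
    image_size: tuple[int, int] = (64, 64),
) -> tuple[np.ndarray, np.ndarray]:
    """Mean shape (P, 2) in image coordinates + orthonormal mode matrix (2P, k).

    The first modes are orthonormalized versions of interpretable
    deformations (width, height, mouth, eye spacing, brows, ...); extra
    modes beyond those are seeded random directions.
    """
    if n_points != N_POINTS:
        raise ConfigError(f"n_points must match the {N_POINTS}-point template")
    if shape_modes < 0 or shape_modes > 2 * n_points:
        raise ConfigError("shape_modes must be in [0, 2 * n_points]")
    mean_shape = template_landmarks(image_size)
    if shape_modes == 0:
        return mean_shape, np.zeros((2 * n_points, 0))
    dirs = _structured_directions(mean_shape)
    rng = np.random.default_rng(seed)
    while len(dirs) < shape_modes:
        dirs.append(rng.standard_normal(2 * n_points))
    basis = np.column_stack(dirs[: max(shape_modes, len(dirs))])
    q, _ = np.linalg.qr(basis)
    q = q[:, :shape_modes]
    # deterministic column signs: largest-magnitude entry positive
    for j in range(q.shape[1]):
        i = int(np.argmax(np.abs(q[:, j])))
        if q[i, j] < 0:
            q[:, j] = -q[:, j]
    return mean_shape, q


# ---------------------------------------------------------------------------
# Rendering


def _ellipse(img: np.ndarray, center_xy, rx: float, ry: float, value: float) -> None:
    rr, cc = skdraw.ellipse(
        center_xy[1], center_xy[0], max(ry, 0.5), max(rx, 0.5), shape=img.shape
    )
    img[rr, cc] = value


def _thick_segment(img: np.ndarray, a_xy, b_xy, half_width: float, value: float) -> None:
    a = np.asarray(a_xy, float)
    b = np.asarray(b_xy, float)
    d = b - a
    n = np.linalg.norm(d)
    if n < 1e-9:
        _ellipse(img, a, half_width, half_width, value)
        return
    normal = np.array([-d[1], d[0]]) / n * half_width
    corners = np.array([a + normal, b + normal, b - normal, a - normal])
    rr, cc = skdraw.polygon(corners[:, 1], corners[:, 0], shape=img.shape)
    img[rr, cc] = value


def render_face(
    landmarks: np.ndarray,
    image_size: tuple[int, int],
    appearance: dict[str, float] | None = None,
) -> np.ndarray:
    """Deterministic 2-D parametric rendering of a face from its landmarks.

    Filled ellipses/polygons for facial parts on a shaded head oval, then a
    light Gaussian smoothing.  Appearance parameters (skin/brow/lip
    intensity, each in [0, 1]) modulate part contrast; with a fixed
    parameter set the image is a deterministic function of the landmarks.
    """
    appearance = appearance or {}
    skin_p = float(appearance.get("skin_intensity", 0.5))
    brow_p = float(appearance.get("brow_intensity", 0.5))
    lip_p = float(appearance.get("lip_intensity", 0.5))

    pts = np.asarray(landmarks, float)
    ix = LANDMARK_INDEX
    img = np.full(image_size, 0.10)

    brow_y = np.mean([pts[ix[n], 1] for n in
                      ("brow_l_outer", "brow_l_inner", "brow_r_inner", "brow_r_outer")])
    chin = pts[ix["chin"]]
    face_h = max(chin[1] - brow_y, 1.0)
    top = brow_y - 0.55 * face_h
    center_y = 0.5 * (top + chin[1])
    center_x = 0.5 * (pts[ix["cheek_l"], 0] + pts[ix["cheek_r"], 0])
    rx = 0.53 * abs(pts[ix["cheek_r"], 0] - pts[ix["cheek_l"], 0])
    ry = 0.5 * (chin[1] - top)

    skin_val = 0.45 + 0.40 * skin_p
    _ellipse(img, (center_x, center_y), rx, ry, skin_val)

    brow_val = max(0.02, skin_val - 0.15 - 0.55 * brow_p)
    _thick_segment(img, pts[ix["brow_l_outer"]], pts[ix["brow_l_inner"]], 1.2, brow_val)
    _thick_segment(img, pts[ix["brow_r_inner"]], pts[ix["brow_r_outer"]], 1.2, brow_val)

    for outer, inner in (("eye_l_outer", "eye_l_inner"), ("eye_r_inner", "eye_r_outer")):
        a, b = pts[ix[outer]], pts[ix[inner]]
        c = 0.5 * (a + b)
        erx = 0.5 * np.linalg.norm(b - a)
        _ellipse(img, c, erx, 0.45 * erx, 0.95)  # sclera
        _ellipse(img, c, 0.45 * erx, 0.40 * erx, 0.12)  # iris/pupil

    _thick_segment(img, pts[ix["nose_bridge"]], pts[ix["nose_tip"]], 0.8, skin_val - 0.12)
    for n in ("nostril_l", "nostril_r"):
        _ellipse(img, pts[ix[n]], 1.0, 0.8, 0.20)

    mouth_c = 0.5 * (pts[ix["mouth_l"]] + pts[ix["mouth_r"]])
    mouth_cy = 0.5 * (pts[ix["lip_upper"], 1] + pts[ix["lip_lower"], 1])
    mrx = 0.5 * np.linalg.norm(pts[ix["mouth_r"]] - pts[ix["mouth_l"]])
    mry = max(0.8, 0.5 * (pts[ix["lip_lower"], 1] - pts[ix["lip_upper"], 1]))
    lip_val = max(0.05, 0.55 - 0.40 * lip_p)
    _ellipse(img, (mouth_c[0], mouth_cy), mrx, mry, lip_val)

    img = gaussian_filter(img, sigma=0.7, mode="nearest")
    return np.clip(img, 0.0, 1.0)


# ---------------------------------------------------------------------------
# Sampling


def _in_bounds(pts: np.ndarray, image_size: tuple[int, int], margin: float = 1.0) -> bool:
    h, w = image_size
    return bool(
        np.all(pts[:, 0] >= margin)
        and np.all(pts[:, 0] <= w - 1 - margin)
        and np.all(pts[:, 1] >= margin)
        and np.all(pts[:, 1] <= h - 1 - margin)
    )


def _sample_appearance(rng: np.random.Generator) -> dict[str, float]:
    return {
        name: float(np.clip(0.5 + 0.22 * rng.standard_normal(), 0.0, 1.0))
        for name in APPEARANCE_PARAMS
    }


def sample_face(
    shape_model: tuple[np.ndarray, np.ndarray],
    config: SyntheticConfig,
    rng: np.random.Generator,
    face_id: str = "face",
) -> FaceSample:
    """Draw one face: landmarks = mean + modes·N(0, mode_sd²), then render.

    Out-of-bounds landmark configurations are resampled up to a retry cap.
    """
    mean_shape, modes = shape_model
    p = mean_shape.shape[0]
    for _ in range(_RETRY_CAP + 1):
        coeffs = rng.normal(0.0, config.mode_sd, size=modes.shape[1])
        pts = mean_shape + (modes @ coeffs).reshape(p, 2)
        if _in_bounds(pts, config.image_size):
            break
    else:
        raise RuntimeError(
            f"could not sample in-bounds landmarks after {_RETRY_CAP} retries; "
            "reduce mode_sd or enlarge image_size"
        )
    appearance = _sample_appearance(rng)
    image = render_face(pts, config.image_size, appearance)
    return FaceSample(id=face_id, image=image, landmarks=pts, appearance=appearance)


def compute_trait_features(sample: FaceSample) -> dict[str, float]:
    """All named features a TraitSpec may reference, for one face."""
    feats = structural_features(sample.landmarks)
    feats.update(sample.appearance)
    return feats


def assign_trait_scores(
    sample: FaceSample,
    trait_specs,
    rng: np.random.Generator,
) -> FaceSample:
    """Fill in sample.scores from the planted generating model."""
    feats = compute_trait_features(sample)
    for spec in trait_specs:
        spec.validate()
        missing = sorted(set(spec.weights) - set(feats))
        if missing:
            raise ConfigError(
                f"trait {spec.trait_name!r}: feature(s) {missing} not computable; "
                f"known features: {sorted(feats)}"
            )
        raw = spec.intercept + sum(w * feats[name] for name, w in spec.weights.items())
        raw += rng.normal(0.0, spec.noise_sd) if spec.noise_sd > 0 else 0.0
        sample.scores[spec.trait_name] = float(np.clip(raw, RATING_MIN, RATING_MAX))
    return sample


def default_trait_specs(
    noise_sd: float = 0.5, image_size: tuple[int, int] = (64, 64)
) -> tuple[TraitSpec, ...]:
    """Planted generating models for the nine traits.

    Weights are scaled to the typical pixel-scale spread of each structural
    measurement under the default shape model, so each planted signal has
    roughly unit score spread against `noise_sd` rating units of rater
    noise.  Traits deliberately share features (brow height and darkness
    across the dominance-like traits, skin tone across the valence-like
    ones) so that the rating matrix has the low-rank correlation structure
    a valence/dominance trait PCA expects.  "Competent" is given a weak
    model on purpose: it should remain hard to predict.
    """
    # Features are in raw units (pixels for structural ones, [0,1] for
    # appearance parameters), so each intercept offsets the template
    # baseline to center typical scores at 5 on the 1-9 scale.
    baseline = structural_features(template_landmarks(image_size))
    baseline.update({name: 0.5 for name in APPEARANCE_PARAMS})

    def mk(name: str, weights: dict[str, float]) -> TraitSpec:
        offset = sum(w * baseline[f] for f, w in weights.items())
        return TraitSpec(name, weights, intercept=5.0 - offset, noise_sd=noise_sd)
    return (
        mk("attractive", {"inter_ocular_distance": 0.30, "eye_width": 0.40, "skin_intensity": 1.2}),
        mk("competent", {"inter_ocular_distance": 0.12, "skin_intensity": 0.4}),
        mk("trustworthy", {"skin_intensity": 0.9, "mouth_width": 0.20, "brow_eye_distance": 0.20}),
        mk("dominant", {"brow_eye_distance": -0.45, "face_width": 0.25, "brow_intensity": 1.5}),
        mk("mean", {"brow_eye_distance": -0.30, "brow_intensity": 1.0, "lip_thickness": -0.20}),
        mk("frightening", {"brow_intensity": 1.3, "brow_eye_distance": -0.25}),
        mk("extroverted", {"mouth_width": 0.35, "lip_thickness": 0.25, "lip_intensity": 0.8}),
        mk("threatening", {"brow_eye_distance": -0.35, "face_width": 0.20, "brow_intensity": 1.2,
                           "mouth_width": -0.10}),
        mk("likable", {"skin_intensity": 1.0, "mouth_width": 0.25, "lip_intensity": 0.4}),
    )


def planted_benchmark_specs(
    noise_sd: float = 0.4, image_size: tuple[int, int] = (64, 64)
) -> tuple[TraitSpec, ...]:
    """Trait models for signal-recovery benchmarks.

    Three traits get sharply controlled generating channels:

    * ``dominant`` — planted strongly in structure *and* appearance
      (brow height, face width, brow darkness): every descriptor family
      should be able to learn it;
    * ``extroverted`` — planted on mouth width alone: the point-importance
      map should light up the mouth corners;
    * ``frightening`` — planted on brow darkness alone (appearance-only):
      invisible to the landmark descriptor, so holistic–structural
      predicted-label correlation should collapse for it.

    The remaining traits keep their default models.
    """
    baseline = structural_features(template_landmarks(image_size))
    baseline.update({name: 0.5 for name in APPEARANCE_PARAMS})

    def mk(name: str, weights: dict[str, float], spec_noise: float) -> TraitSpec:
        offset = sum(w * baseline[f] for f, w in weights.items())
        return TraitSpec(name, weights, intercept=5.0 - offset, noise_sd=spec_noise)

    overrides = {
        "dominant": mk(
            "dominant",
            {"brow_eye_distance": -0.6, "face_width": 0.3, "brow_intensity": 2.0},
            0.75 * noise_sd,
        ),
        "extroverted": mk("extroverted", {"mouth_width": 0.5}, 0.5 * noise_sd),
        "frightening": mk("frightening", {"brow_intensity": 2.0}, 0.75 * noise_sd),
    }
    return tuple(
        overrides.get(s.trait_name, s)
        for s in default_trait_specs(noise_sd=noise_sd, image_size=image_size)
    )


# ---------------------------------------------------------------------------
# Dataset generation


def generate_dataset(
    config: SyntheticConfig,
    out_dir: str | Path | None = None,
    overwrite: bool = False,
) -> tuple[list[FaceSample], dict]:
    """Generate n_faces samples; optionally write them to disk.

    On-disk layout: ``images/<id>.png`` (8-bit grayscale), ``landmarks.csv``
    (``id,x1,y1,…,x21,y21``), ``scores.csv`` (``id,<trait columns>``) and a
    YAML ``manifest.yaml`` recording the full config and seed.
    """
    config.validate()
    specs = config.resolved_trait_specs()
    rng = np.random.default_rng(config.seed)
    model = build_shape_model(
        config.n_points, config.shape_modes, seed=config.seed, image_size=config.image_size
    )
    width = max(4, len(str(config.n_faces - 1)))
    samples = []
    for i in range(config.n_faces):
        s = sample_face(model, config, rng, face_id=f"face_{i:0{width}d}")
        assign_trait_scores(s, specs, rng)
        samples.append(s)

    manifest = {
        "generator": "facetraits.synthetic_faces",
        "seed": config.seed,
        "n_faces": config.n_faces,
        "config": _config_to_dict(config),
    }

    if out_dir is not None:
        _write_dataset(samples, manifest, Path(out_dir), overwrite=overwrite)
    return samples, manifest


def _config_to_dict(config: SyntheticConfig) -> dict:
    d = dataclasses.asdict(config)
    d["image_size"] = list(config.image_size)
    d["trait_specs"] = [
        {
            "trait_name": s.trait_name,
            "weights": dict(s.weights),
            "intercept": s.intercept,
            "noise_sd": s.noise_sd,
        }
        for s in config.resolved_trait_specs()
    ]
    return d


def _write_dataset(samples, manifest, out_dir: Path, overwrite: bool) -> None:
    import pandas as pd
    import yaml
    from PIL import Image

    if out_dir.exists() and any(out_dir.iterdir()) and not overwrite:
        raise FileExistsError(
            f"output directory {out_dir} exists and is not empty (pass overwrite=True)"
        )
    (out_dir / "images").mkdir(parents=True, exist_ok=True)

    n_pts = samples[0].landmarks.shape[0]
    lm_cols = ["id"] + [f"{ax}{i + 1}" for i in range(n_pts) for ax in ("x", "y")]
    lm_rows = []
    score_rows = []
    traits = [spec_name for spec_name in samples[0].scores]
    for s in samples:
        arr = (np.clip(s.image, 0, 1) * 255).round().astype(np.uint8)
        Image.fromarray(arr, mode="L").save(out_dir / "images" / f"{s.id}.png")
        lm_rows.append([s.id] + [float(v) for v in s.landmarks.ravel()])
        score_rows.append([s.id] + [s.scores[t] for t in traits])
    pd.DataFrame(lm_rows, columns=lm_cols).to_csv(
        out_dir / "landmarks.csv", index=False, float_format="%.4f"
    )
    pd.DataFrame(score_rows, columns=["id"] + traits).to_csv(
        out_dir / "scores.csv", index=False, float_format="%.4f"
    )
    with open(out_dir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
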