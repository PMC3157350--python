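"""Structural (landmark-geometry) face descriptor.

A face is reduced to the ordered coordinates of P fiducial points.  The
descriptor concatenates three blocks of relations:

1. each point relative to its own mean-shape position, in polar form
   (radius, angle) — 2P values;
2. each point relative to *every* point of the mean shape, in polar form
   — 2P² values;
3. the Euclidean distances between all point pairs within the face
   — P(P−1)/2 values.

Total length D = 2P + 2P² + P(P−1)/2, i.e. 1134 for the 21-point template.
Every descriptor entry carries a provenance record (which landmarks it
touches and whether it is a radius, an angle or a distance) so that
feature-level statistics can later be mapped back onto the face.

Angle convention: ``atan2(dy, dx)`` in image coordinates (y downward),
radians in (−π, π], defined as 0 when the radius is 0.

Orderings are fixed: block 2 is row-major in (i, j); block 3 enumerates
pairs i < j lexicographically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "MeanShape",
    "FeatureMap",
    "GeometricDescriptor",
    "compute_mean_shape",
    "polar_diff",
    "geometric_descriptor",
    "descriptor_length",
    "build_feature_map",
    "feature_kind_partition",
]

KINDS = ("radius", "angle", "distance")


class ShapeMismatchError(ValueError):
    """Landmark sets do not share the template's point count/ordering."""


@dataclass(frozen=True)
class MeanShape:
    """Coordinate-wise mean landmark configuration of a face set."""

    points: np.ndarray  # (P, 2)

    @property
    def n_points(self) -> int:
        return self.points.shape[0]


@dataclass(frozen=True)
class FeatureMap:
    """Provenance of each descriptor entry.

    kinds[k] in {"radius", "angle", "distance"}; points[k] is the tuple of
    landmark indices involved in entry k; names[k] is a stable column name
    (``s1_r_05``, ``s2_a_03_17``, ``s3_d_02_09``).
    """

    kinds: tuple[str, ...]
    points: tuple[tuple[int, ...], ...]
    names: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.kinds)


@dataclass(frozen=True)
class GeometricDescriptor:
    values: np.ndarray
    feature_map: FeatureMap


def descriptor_length(n_points: int) -> int:
    """Closed-form descriptor length: 2P + 2P² + P(P−1)/2."""
    p = n_points
    return 2 * p + 2 * p * p + p * (p - 1) // 2


def compute_mean_shape(landmark_sets) -> MeanShape:
    """Coordinate-wise arithmetic mean over a collection of landmark sets."""
    arrs = [np.asarray(s, dtype=float) for s in landmark_sets]
    if not arrs:
        raise ValueError("need at least one landmark set")
    p = arrs[0].shape
    for a in arrs:
        if a.shape != p:
            raise ShapeMismatchError(f"inconsistent landmark shapes: {a.shape} vs {p}")
    return MeanShape(points=np.mean(arrs, axis=0))


def polar_diff(p, q) -> tuple[float, float]:
    """Polar coordinates (radius, angle) of the difference p − q."""
    dx = float(p[0]) - float(q[0])
    dy = float(p[1]) - float(q[1])
    r = math.hypot(dx, dy)
    a = math.atan2(dy, dx) if r > 0.0 else 0.0
    return r, a


def build_feature_map(n_points: int) -> FeatureMap:
    """Feature-map skeleton for a P-point template (values-independent)."""
    kinds: list[str] = []
    points: list[tuple[int, ...]] = []
    names: list[str] = []
    for i in range(n_points):
        kinds += ["radius", "angle"]
        points += [(i,), (i,)]
        names += [f"s1_r_{i:02d}", f"s1_a_{i:02d}"]
    for i in range(n_points):
        for j in range(n_points):
            kinds += ["radius", "angle"]
            points += [(i, j), (i, j)]
            names += [f"s2_r_{i:02d}_{j:02d}", f"s2_a_{i:02d}_{j:02d}"]
    for i in range(n_points):
        for j in range(i + 1, n_points):
            kinds.append("distance")
            points.append((i, j))
            names.append(f"s3_d_{i:02d}_{j:02d}")
    return FeatureMap(kinds=tuple(kinds), points=tuple(points), names=tuple(names))


def geometric_descriptor(landmarks, mean_shape: MeanShape) -> GeometricDescriptor:
    """Three-block structural descriptor of one face.

    ``landmarks`` is (P, 2); ``mean_shape`` must use the same ordering.
    """
    pts = np.asarray(landmarks, dtype=float)
    mean = np.asarray(mean_shape.points, dtype=float)
    if pts.shape != mean.shape or pts.ndim != 2 or pts.shape[1] != 2:
        raise ShapeMismatchError(
            f"landmarks shape {pts.shape} does not match mean shape {mean.shape}"
        )
    p = pts.shape[0]
    values = np.empty(descriptor_length(p))
    k = 0
    for i in range(p):
        r, a = polar_diff(pts[i], mean[i])
        values[k] = r
        values[k + 1] = a
        k += 2
    for i in range(p):
        for j in range(p):
            r, a = polar_diff(pts[i], mean[j])
            values[k] = r
            values[k + 1] = a
            k += 2
    for i in range(p):
        for j in range(i + 1, p):
            values[k] = float(np.linalg.norm(pts[i] - pts[j]))
            k += 1
    return GeometricDescriptor(values=values, feature_map=build_feature_map(p))


def feature_kind_partition(feature_map, mask=None) -> dict[str, int]:
    """Count descriptor entries per kind, optionally within a boolean mask.

    Accepts a FeatureMap or a GeometricDescriptor.
    """
    if isinstance(feature_map, GeometricDescriptor):
        feature_map = feature_map.feature_map
    kinds = np.asarray(feature_map.kinds)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != kinds.shape:
            raise ValueError("mask length does not match feature map")
        kinds = kinds[mask]
    return {kind: int(np.sum(kinds == kind)) for kind in KINDS}
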