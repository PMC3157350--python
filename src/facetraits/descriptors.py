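"""Featurizers: fit-on-training-fold descriptor pipelines over face samples.

Each featurizer implements ``fit(samples)`` / ``transform(samples)`` so
that everything estimated from data (the mean landmark shape, the
reference face used for shape normalization, the eigen-basis) is computed
on the training fold only — nfold_cv refits the featurizer per fold.

Shape-normalized images are cached per (sample id, reference) because the
reference face rarely changes between folds and the piecewise-affine warp
dominates the cost.
"""

from __future__ import annotations

import numpy as np

from .appearance import (
    EigenModel,
    HOGParams,
    ReferenceShape,
    choose_reference,
    fit_eigenfaces,
    hog_descriptor,
    project_eigenfaces,
    shape_normalize,
)
from .geometry import MeanShape, build_feature_map, compute_mean_shape, geometric_descriptor

__all__ = ["GeometricFeaturizer", "EigenFeaturizer", "HOGFeaturizer", "make_featurizer"]


class GeometricFeaturizer:
    """Structural descriptor relative to the training-fold mean shape."""

    def __init__(self):
        self.mean_shape_: MeanShape | None = None

    def fit(self, samples):
        self.mean_shape_ = compute_mean_shape([s.landmarks for s in samples])
        return self

    def transform(self, samples) -> np.ndarray:
        if self.mean_shape_ is None:
            raise RuntimeError("featurizer is not fitted")
        return np.stack(
            [geometric_descriptor(s.landmarks, self.mean_shape_).values for s in samples]
        )

    def feature_names(self):
        return build_feature_map(self.mean_shape_.n_points).names


class _WarpCache:
    """Shape-normalized image cache keyed by (sample id, reference bytes)."""

    def __init__(self):
        self._store: dict[tuple, np.ndarray] = {}

    def warped(self, sample, reference: ReferenceShape) -> np.ndarray:
        key = (sample.id, reference.landmarks.tobytes())
        if key not in self._store:
            self._store[key] = shape_normalize(sample.image, sample.landmarks, reference)
        return self._store[key]


class _ShapeNormalizedBase:
    def __init__(self):
        self.reference_: ReferenceShape | None = None
        self._cache = _WarpCache()

    def _fit_reference(self, samples):
        mean = compute_mean_shape([s.landmarks for s in samples])
        _, self.reference_ = choose_reference(
            [s.landmarks for s in samples], mean.points, samples[0].image.shape
        )

    def _warped(self, samples):
        if self.reference_ is None:
            raise RuntimeError("featurizer is not fitted")
        return [self._cache.warped(s, self.reference_) for s in samples]


class EigenFeaturizer(_ShapeNormalizedBase):
    """EigenFaces coefficients of shape-normalized images."""

    def __init__(self, variance_fraction: float = 0.95):
        super().__init__()
        self.variance_fraction = variance_fraction
        self.model_: EigenModel | None = None

    def fit(self, samples):
        self._fit_reference(samples)
        self.model_ = fit_eigenfaces(self._warped(samples), self.variance_fraction)
        return self

    def transform(self, samples) -> np.ndarray:
        if self.model_ is None:
            raise RuntimeError("featurizer is not fitted")
        return np.stack([project_eigenfaces(self.model_, im) for im in self._warped(samples)])

    def feature_names(self):
        return tuple(f"eig_{i:03d}" for i in range(self.model_.n_components))


class HOGFeaturizer(_ShapeNormalizedBase):
    """Dense-grid HOG of shape-normalized images."""

    def __init__(self, params: HOGParams | None = None):
        super().__init__()
        self.params = params or HOGParams()

    def fit(self, samples):
        self._fit_reference(samples)
        h, w = samples[0].image.shape
        if h != w or h != self.params.window:
            self.params = HOGParams(
                window=h,
                cell=self.params.cell,
                block=self.params.block,
                overlap=self.params.overlap,
                n_bins=self.params.n_bins,
                epsilon=self.params.epsilon,
            )
            self.params.validate()
        return self

    def transform(self, samples) -> np.ndarray:
        return np.stack([hog_descriptor(im, self.params) for im in self._warped(samples)])

    def feature_names(self):
        from .appearance import hog_length

        return tuple(f"hog_{i:04d}" for i in range(hog_length(self.params)))


DESCRIPTOR_NAMES = ("geometric", "eigenfaces", "hog")


def make_featurizer(name: str, *, variance_fraction: float = 0.95, hog_params=None):
    if name == "geometric":
        return GeometricFeaturizer()
    if name == "eigenfaces":
        return EigenFeaturizer(variance_fraction=variance_fraction)
    if name == "hog":
        return HOGFeaturizer(params=hog_params)
    raise ValueError(f"unknown descriptor {name!r}; choose from {DESCRIPTOR_NAMES}")
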