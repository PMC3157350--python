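"""Holistic appearance descriptors on shape-normalized faces.

To measure appearance independently of facial structure, every face is
first warped so its landmarks coincide with those of a reference face (the
training face closest to the mean shape).  Two holistic descriptors are
then computed on the normalized images:

* **EigenFaces** — principal components of the vectorized images; a face's
  descriptor is its vector of projection coefficients onto the retained
  eigen-basis.
* **HOG** — the concatenation of block-normalized, per-cell histograms of
  unsigned gradient orientations (folded into [0°, 180°)), computed on a
  uniform cell grid with overlapping normalization blocks.

The warp is an exact landmark-driven piecewise-affine map over a Delaunay
triangulation of the reference landmarks plus 8 fixed border anchors;
landmarks map onto their reference positions exactly (up to interpolation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay
from skimage.transform import PiecewiseAffineTransform, warp

__all__ = [
    "ReferenceShape",
    "EigenModel",
    "HOGParams",
    "choose_reference",
    "shape_normalize",
    "fit_eigenfaces",
    "project_eigenfaces",
    "reconstruct_eigenfaces",
    "hog_descriptor",
    "hog_length",
]


class DegenerateTriangleError(ValueError):
    """The warp triangulation contains a (near-)collinear triangle."""


@dataclass(frozen=True)
class ReferenceShape:
    """Landmarks of the reference face all images are warped onto."""

    landmarks: np.ndarray  # (P, 2) pixel (x, y)
    image_size: tuple[int, int]
    selection: dict = field(default_factory=dict)  # how the face was chosen


def choose_reference(landmark_sets, mean_points: np.ndarray, image_size) -> tuple[int, ReferenceShape]:
    """Pick the face whose landmarks minimize summed distance to the mean shape."""
    best, best_cost = -1, np.inf
    for i, pts in enumerate(landmark_sets):
        cost = float(np.linalg.norm(np.asarray(pts, float) - mean_points, axis=1).sum())
        if cost < best_cost:
            best, best_cost = i, cost
    ref = ReferenceShape(
        landmarks=np.asarray(landmark_sets[best], float).copy(),
        image_size=tuple(image_size),
        selection={"rule": "min_summed_distance_to_mean", "index": best, "cost": best_cost},
    )
    return best, ref


def _border_anchors(image_size: tuple[int, int]) -> np.ndarray:
    h, w = image_size
    x1, y1 = w - 1.0, h - 1.0
    return np.array(
        [
            (0.0, 0.0), (x1 / 2, 0.0), (x1, 0.0),
            (0.0, y1 / 2), (x1, y1 / 2),
            (0.0, y1), (x1 / 2, y1), (x1, y1),
        ]
    )


def shape_normalize(
    image: np.ndarray,
    landmarks: np.ndarray,
    reference: ReferenceShape,
) -> np.ndarray:
    """Warp ``image`` so its landmarks land on the reference positions.

    Piecewise-affine over a Delaunay triangulation of reference landmarks +
    8 border anchors (anchors map to themselves, so the frame stays put).
    Output has the reference image size.
    """
    landmarks = np.asarray(landmarks, float)
    ref_pts = np.asarray(reference.landmarks, float)
    if landmarks.shape != ref_pts.shape:
        raise ValueError(
            f"landmark shape {landmarks.shape} does not match reference {ref_pts.shape}"
        )
    anchors = _border_anchors(reference.image_size)
    dst = np.vstack([ref_pts, anchors])  # output-plane control points
    src = np.vstack([landmarks, anchors])  # input-plane control points

    tri = Delaunay(dst)
    for simplex in tri.simplices:
        for plane in (dst, src):
            a, b, c = plane[simplex]
            area = 0.5 * abs((b[0] - a[0]) * (c[1] - a[1]) - (c[0] - a[0]) * (b[1] - a[1]))
            if area < 1e-9:
                raise DegenerateTriangleError(
                    f"degenerate triangle between control points "
                    f"{tuple(int(i) for i in simplex)}"
                )

    if hasattr(PiecewiseAffineTransform, "from_estimate"):
        tform = PiecewiseAffineTransform.from_estimate(dst, src)  # output -> input coords
        if not tform:
            raise DegenerateTriangleError("piecewise-affine estimation failed")
    else:  # older scikit-image
        tform = PiecewiseAffineTransform()
        if not tform.estimate(dst, src):
            raise DegenerateTriangleError("piecewise-affine estimation failed")
    out = warp(
        np.asarray(image, float),
        tform,
        output_shape=reference.image_size,
        order=1,
        mode="edge",
        preserve_range=True,
    )
    return out


# ---------------------------------------------------------------------------
# EigenFaces


@dataclass(frozen=True)
class EigenModel:
    mean: np.ndarray  # (D,) training mean image vector
    components: np.ndarray  # (k, D), orthonormal rows, variance-ordered
    eigenvalues: np.ndarray  # all positive eigenvalues, non-increasing
    variance_fraction: float
    image_size: tuple[int, int]

    @property
    def n_components(self) -> int:
        return self.components.shape[0]


def _vectorize(images) -> np.ndarray:
    mats = [np.asarray(im, float) for im in images]
    shape = mats[0].shape
    for m in mats:
        if m.shape != shape:
            raise ValueError("images must share one size")
    return np.stack([m.ravel() for m in mats]), shape


def fit_eigenfaces(images, variance_fraction: float = 0.95) -> EigenModel:
    """PCA of vectorized images, retaining the smallest k components whose
    cumulative eigenvalue share reaches ``variance_fraction``."""
    if not (0.0 < variance_fraction <= 1.0):
        raise ValueError("variance_fraction must be in (0, 1]")
    x, shape = _vectorize(images)
    if x.shape[0] < 2:
        raise ValueError("need at least two images")
    mean = x.mean(axis=0)
    xc = x - mean
    # SVD of the centered data; eigenvalues of the covariance are s^2/(n-1)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    eigvals = s**2 / (x.shape[0] - 1)
    keep = eigvals > max(eigvals[0], 1.0) * 1e-12 if eigvals.size else np.zeros(0, bool)
    eigvals = eigvals[keep]
    vt = vt[keep]
    shares = np.cumsum(eigvals) / eigvals.sum()
    k = int(np.searchsorted(shares, variance_fraction - 1e-12) + 1)
    k = min(k, len(eigvals))
    comps = vt[:k]
    # deterministic sign: largest-|.| entry of each component positive
    for j in range(comps.shape[0]):
        i = int(np.argmax(np.abs(comps[j])))
        if comps[j, i] < 0:
            comps[j] = -comps[j]
    return EigenModel(
        mean=mean,
        components=comps,
        eigenvalues=eigvals,
        variance_fraction=variance_fraction,
        image_size=shape,
    )


def project_eigenfaces(model: EigenModel, image: np.ndarray) -> np.ndarray:
    """Coefficients of the centered image in the retained eigen-basis."""
    vec = np.asarray(image, float).ravel()
    if vec.shape[0] != model.mean.shape[0]:
        raise ValueError(
            f"image size {np.asarray(image).shape} does not match model {model.image_size}"
        )
    return model.components @ (vec - model.mean)


def reconstruct_eigenfaces(model: EigenModel, coefficients: np.ndarray) -> np.ndarray:
    """Image reconstructed from eigen-coefficients (returns the 2-D grid)."""
    vec = model.mean + np.asarray(coefficients, float) @ model.components
    return vec.reshape(model.image_size)


# ---------------------------------------------------------------------------
# HOG


@dataclass(frozen=True)
class HOGParams:
    """Dense-grid HOG geometry.

    window: square window side in pixels (the full face crop);
    cell: cell side in pixels; block: block side in cells;
    overlap: cells shared between adjacent blocks (stride = block − overlap);
    n_bins: orientation bins evenly spaced over 180° (unsigned gradient).
    """

    window: int = 64
    cell: int = 8
    block: int = 2
    overlap: int = 1
    n_bins: int = 9
    epsilon: float = 1e-6

    def validate(self) -> None:
        if self.window % self.cell != 0:
            raise ValueError("window must be divisible by cell size")
        if not (0 <= self.overlap < self.block):
            raise ValueError("overlap must satisfy 0 <= overlap < block")
        if self.n_bins < 1:
            raise ValueError("n_bins must be >= 1")

    @property
    def cells_per_side(self) -> int:
        return self.window // self.cell

    @property
    def blocks_per_side(self) -> int:
        stride = self.block - self.overlap
        return (self.cells_per_side - self.block) // stride + 1


def hog_length(params: HOGParams) -> int:
    """Descriptor length from the block-grid counting formula."""
    params.validate()
    nb = params.blocks_per_side
    return nb * nb * params.block * params.block * params.n_bins


def hog_descriptor(image: np.ndarray, params: HOGParams = HOGParams()) -> np.ndarray:
    """Unsigned-gradient HOG over a uniform cell grid with overlapping blocks.

    Gradients by central differences on a replicate-padded image;
    orientations folded into [0°, 180°) with magnitude-weighted linear
    interpolation between the two nearest bin centers (centers at
    i·180/n_bins); per-block concatenated cell histograms are
    L2-normalized with an epsilon; the final vector concatenates all
    (overlapping) blocks in row-major block order.
    """
    params.validate()
    img = np.asarray(image, float)
    if img.shape != (params.window, params.window):
        raise ValueError(f"image shape {img.shape} != window {(params.window, params.window)}")

    padded = np.pad(img, 1, mode="edge")
    gx = 0.5 * (padded[1:-1, 2:] - padded[1:-1, :-2])
    gy = 0.5 * (padded[2:, 1:-1] - padded[:-2, 1:-1])
    mag = np.hypot(gx, gy)
    ang = np.degrees(np.arctan2(gy, gx)) % 180.0  # unsigned orientation

    n_bins, cell = params.n_bins, params.cell
    bin_width = 180.0 / n_bins
    pos = ang / bin_width  # bin centers at i * bin_width
    lo = np.floor(pos).astype(int)
    frac = pos - lo
    lo_bin = lo % n_bins
    hi_bin = (lo + 1) % n_bins

    nc = params.cells_per_side
    cell_hist = np.zeros((nc, nc, n_bins))
    rows = np.repeat(np.arange(params.window) // cell, params.window).reshape(
        params.window, params.window
    )
    cols = rows.T
    np.add.at(cell_hist, (rows, cols, lo_bin), mag * (1.0 - frac))
    np.add.at(cell_hist, (rows, cols, hi_bin), mag * frac)

    stride = params.block - params.overlap
    nb = params.blocks_per_side
    out = []
    for by in range(0, nb * stride, stride):
        for bx in range(0, nb * stride, stride):
            block = cell_hist[by : by + params.block, bx : bx + params.block].ravel()
            out.append(block / np.sqrt(np.sum(block**2) + params.epsilon**2))
    return np.concatenate(out)
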