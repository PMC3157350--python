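"""Second-level analyses on top of the descriptor/classifier pipeline.

* correlation of the ±1 labels predicted by two descriptor pipelines
  (Pearson on ±1 codes, i.e. the phi coefficient) — do holistic and
  structural models label the same faces the same way?
* per-feature correlation of the geometric descriptor with the trait
  labels, mapped back onto landmarks as a point-importance map (how often
  each landmark participates in the highly correlated features);
* the share of angle vs distance features among the selected ones;
* PCA of the trait-score matrix (the first two components play the role
  of the valence/dominance dimensions of trait-judgment space);
* ranking unseen faces by classifier confidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import FeatureMap, feature_kind_partition

__all__ = [
    "PointImportanceMap",
    "TraitPCA",
    "prediction_label_correlation",
    "feature_trait_correlation",
    "point_importance",
    "angle_vs_distance_share",
    "trait_pca_projection",
    "rank_by_confidence",
    "plot_point_importance",
]


def prediction_label_correlation(pred_a, pred_b) -> float:
    """Pearson correlation of two aligned ±1 label vectors (phi coefficient).

    Returns 0.0 when either vector is constant (undefined correlation).
    """
    a = np.asarray(pred_a, float)
    b = np.asarray(pred_b, float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("prediction vectors must be 1-D and aligned")
    if a.size < 2:
        raise ValueError("need at least two samples")
    if set(np.unique(a)) - {-1.0, 1.0} or set(np.unique(b)) - {-1.0, 1.0}:
        raise ValueError("predictions must be coded ±1")
    if a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def feature_trait_correlation(descriptor_matrix, labels) -> tuple[np.ndarray, np.ndarray]:
    """Per-column Pearson correlation with a ±1 label vector.

    Returns (coefficients, constant_flags); constant columns get
    coefficient 0 and a True flag.
    """
    x = np.asarray(descriptor_matrix, float)
    y = np.asarray(labels, float)
    if x.ndim != 2 or x.shape[0] != y.shape[0]:
        raise ValueError("descriptor matrix rows must match the label vector")
    xc = x - x.mean(axis=0)
    yc = y - y.mean()
    sx = xc.std(axis=0)
    sy = yc.std()
    flags = sx == 0
    denom = np.where(flags, 1.0, sx) * (sy if sy > 0 else 1.0) * x.shape[0]
    coeffs = (xc * yc[:, None]).sum(axis=0) / denom
    coeffs[flags] = 0.0
    if sy == 0:
        coeffs[:] = 0.0
        flags = np.ones_like(flags)
    return coeffs, flags


@dataclass(frozen=True)
class PointImportanceMap:
    trait: str
    raw_counts: np.ndarray  # per landmark
    normalized: np.ndarray  # raw / max, in [0, 1]; zeros if nothing selected
    selected: np.ndarray  # selected feature indices
    threshold: float
    threshold_mode: str


def _select_features(coefficients, threshold: float, mode: str) -> np.ndarray:
    coeffs = np.abs(np.asarray(coefficients, float))
    if mode == "quantile":
        if not (0.0 <= threshold <= 1.0):
            raise ValueError("quantile threshold must be in [0, 1]")
        cut = np.quantile(coeffs, threshold) if threshold > 0 else -np.inf
        return np.flatnonzero(coeffs >= cut) if threshold > 0 else np.arange(coeffs.size)
    if mode == "absolute":
        return np.flatnonzero(coeffs > threshold)
    raise ValueError("threshold mode must be 'quantile' or 'absolute'")


def point_importance(
    coefficients,
    feature_map: FeatureMap,
    threshold: float = 0.95,
    mode: str = "quantile",
    trait: str = "",
    n_points: int | None = None,
) -> PointImportanceMap:
    """Count, per landmark, the selected features it participates in.

    Features whose |correlation| passes the threshold (a quantile cut by
    default, or an absolute cut) each add 1 to every landmark recorded for
    them in the feature map; counts are normalized by their maximum.
    """
    coeffs = np.asarray(coefficients, float)
    if coeffs.size != len(feature_map):
        raise ValueError("coefficients length does not match the feature map")
    selected = _select_features(coeffs, threshold, mode)
    if n_points is None:
        n_points = 1 + max(max(pts) for pts in feature_map.points)
    counts = np.zeros(n_points)
    for k in selected:
        for p in feature_map.points[k]:
            counts[p] += 1.0
    if selected.size == 0:
        import warnings

        warnings.warn(f"no feature selected for trait {trait!r}; importance map is empty")
        normalized = counts.copy()
    else:
        normalized = counts / counts.max() if counts.max() > 0 else counts.copy()
    return PointImportanceMap(
        trait=trait,
        raw_counts=counts,
        normalized=normalized,
        selected=selected,
        threshold=threshold,
        threshold_mode=mode,
    )


def angle_vs_distance_share(
    coefficients, feature_map: FeatureMap, threshold: float = 0.95, mode: str = "quantile"
) -> dict:
    """Kind composition of the selected features (radius/angle/distance)."""
    selected = _select_features(np.asarray(coefficients, float), threshold, mode)
    mask = np.zeros(len(feature_map), bool)
    mask[selected] = True
    counts = feature_kind_partition(feature_map, mask)
    total = sum(counts.values())
    shares = {k: (v / total if total else 0.0) for k, v in counts.items()}
    ratio = (
        counts["angle"] / counts["distance"] if counts["distance"] > 0 else float("inf")
    ) if counts["angle"] > 0 or counts["distance"] > 0 else float("nan")
    return {"counts": counts, "shares": shares, "angle_to_distance_ratio": ratio}


@dataclass(frozen=True)
class TraitPCA:
    components: np.ndarray  # (n_retained_traits, n_components) loadings
    projections: np.ndarray  # (n_faces, 2)
    variance_shares: np.ndarray  # over all components of the retained traits
    trait_names: tuple[str, ...]  # retained (varying) traits
    dropped: tuple[str, ...] = field(default_factory=tuple)  # zero-variance traits


def trait_pca_projection(trait_score_matrix, trait_names=None) -> TraitPCA:
    """Eigen-decomposition of the trait correlation matrix.

    Columns are standardized; zero-variance traits are dropped (flagged).
    Returns all-component variance shares plus per-face projections on the
    first two components (the valence/dominance plane).
    """
    x = np.asarray(trait_score_matrix, float)
    if x.ndim != 2 or x.shape[0] < 3:
        raise ValueError("need an (n_faces >= 3) x n_traits matrix")
    names = tuple(trait_names) if trait_names is not None else tuple(
        f"trait_{i}" for i in range(x.shape[1])
    )
    sd = x.std(axis=0)
    keep = sd > 0
    if keep.sum() < 1:
        raise ValueError("all traits have zero variance")
    z = (x[:, keep] - x[:, keep].mean(axis=0)) / sd[keep]
    corr = (z.T @ z) / x.shape[0]
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    for j in range(eigvecs.shape[1]):  # deterministic sign
        i = int(np.argmax(np.abs(eigvecs[:, j])))
        if eigvecs[i, j] < 0:
            eigvecs[:, j] = -eigvecs[:, j]
    shares = eigvals / eigvals.sum()
    n_proj = min(2, eigvecs.shape[1])
    proj = z @ eigvecs[:, :n_proj]
    if n_proj < 2:
        proj = np.column_stack([proj, np.zeros(len(proj))])
    return TraitPCA(
        components=eigvecs,
        projections=proj,
        variance_shares=shares,
        trait_names=tuple(np.asarray(names)[keep]),
        dropped=tuple(np.asarray(names)[~keep]),
    )


def rank_by_confidence(model, descriptor_matrix, ids=None):
    """Order samples by descending classifier confidence (stable id tie-break).

    Returns a list of (id, confidence) pairs.
    """
    x = np.asarray(descriptor_matrix, float)
    scores = np.asarray(model.confidence(x), float)
    if ids is None:
        ids = [str(i) for i in range(len(scores))]
    ids = list(ids)
    order = sorted(range(len(scores)), key=lambda i: (-scores[i], ids[i]))
    return [(ids[i], float(scores[i])) for i in order]


def plot_point_importance(
    importance: PointImportanceMap,
    mean_points: np.ndarray,
    background: np.ndarray | None = None,
    path=None,
    max_radius: float = 6.0,
):
    """Render the importance map as colored circles over the mean face.

    Circle radius and color (jet colormap) scale with the normalized
    per-landmark count, as in the usual point-importance figures.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pts = np.asarray(mean_points, float)
    fig, ax = plt.subplots(figsize=(4, 4))
    if background is not None:
        ax.imshow(background, cmap="gray", vmin=0, vmax=1)
    norm = importance.normalized
    cmap = plt.get_cmap("jet")
    for (x, y), v in zip(pts, norm):
        ax.add_patch(
            plt.Circle((x, y), radius=0.5 + max_radius * v, color=cmap(v), alpha=0.75)
        )
    ax.set_title(f"Point importance: {importance.trait or 'trait'}")
    ax.set_aspect("equal")
    if background is None:
        ax.invert_yaxis()
    ax.set_xticks([])
    ax.set_yticks([])
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig
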