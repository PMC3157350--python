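"""End-to-end experiment: simulate/load → featurize → evaluate → correlate.

``run_experiment`` ties the stages together: obtain a dataset (synthetic or
from disk), binarize each trait's ratings, cross-validate every requested
descriptor × classifier pair, correlate the labels predicted by the
holistic and structural pipelines, map feature–label correlations onto
landmarks, and run the trait PCA.  All outputs plus a manifest recording
the full configuration are written to the output directory; a fixed seed
makes the run byte-reproducible.
"""

from __future__ import annotations

import dataclasses
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .analysis import (
    PointImportanceMap,
    TraitPCA,
    angle_vs_distance_share,
    feature_trait_correlation,
    plot_point_importance,
    point_importance,
    prediction_label_correlation,
    trait_pca_projection,
)
from .appearance import HOGParams
from .classification import METHODS, ClassifierSpec, CVResult, binarize_scores, nfold_cv
from .descriptors import DESCRIPTOR_NAMES, GeometricFeaturizer, make_featurizer
from .geometry import build_feature_map
from .io import read_dataset
from .synthetic_faces import TRAITS, SyntheticConfig, generate_dataset
from .template import N_POINTS

__all__ = ["ExperimentConfig", "ExperimentResult", "run_experiment"]

log = logging.getLogger("facetraits")

CSV_FLOATS = "%.6f"


@dataclass(frozen=True)
class ExperimentConfig:
    dataset_dir: str | None = None
    synthetic: SyntheticConfig | None = None  # used when dataset_dir is None
    descriptors: tuple[str, ...] = DESCRIPTOR_NAMES
    classifiers: tuple[str, ...] = METHODS
    traits: tuple[str, ...] = TRAITS
    n_folds: int = 10
    binarize_fraction: float = 1.0 / 3.0
    level: float = 0.95
    ci_multiplier: str = "t"
    variance_fraction: float = 0.95
    hog: HOGParams = field(default_factory=HOGParams)
    classifier_params: dict = field(default_factory=dict)  # method -> kwargs
    correlation_classifier: str = "svm_rbf"
    importance_threshold: float = 0.95
    importance_mode: str = "quantile"
    permute_labels: bool = False  # null experiment: shuffle scores across faces
    out_dir: str | None = None
    overwrite: bool = False
    write_figures: bool = True
    seed: int = 0

    def validate(self) -> None:
        for d in self.descriptors:
            if d not in DESCRIPTOR_NAMES:
                raise ValueError(f"unknown descriptor {d!r}; choose from {DESCRIPTOR_NAMES}")
        for c in self.classifiers:
            if c not in METHODS:
                raise ValueError(f"unknown classifier {c!r}; choose from {METHODS}")
        for t in self.traits:
            if t not in TRAITS:
                raise ValueError(f"unknown trait {t!r}; choose from {TRAITS}")
        if not (0.0 < self.binarize_fraction <= 0.5):
            raise ValueError("binarize_fraction must be in (0, 0.5]")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.correlation_classifier not in self.classifiers:
            raise ValueError("correlation_classifier must be one of the selected classifiers")
        self.hog.validate()
        if self.synthetic is not None:
            self.synthetic.validate()


@dataclass
class ExperimentResult:
    config: ExperimentConfig
    n_samples: int
    accuracy_tables: dict  # descriptor -> DataFrame (rows classifiers, cols traits)
    cv_results: dict  # (descriptor, classifier, trait) -> CVResult
    correlations: pd.DataFrame  # predicted-label phi per trait and descriptor pair
    importance: dict  # trait -> {"map": PointImportanceMap, "kinds": dict}
    trait_pca: TraitPCA
    summary: pd.DataFrame  # per trait: best accuracy, learnable flag
    manifest: dict
    out_dir: Path | None


def _combo_seed(base_seed: int, *parts: str) -> int:
    tag = ":".join(str(p) for p in parts)
    return (base_seed * 2654435761 + zlib.crc32(tag.encode())) % (2**31)


def _cell(mean: float, ci: float) -> str:
    return f"{mean:.2f} ({ci:.1f})"


def run_experiment(config: ExperimentConfig) -> ExperimentResult:
    config.validate()
    t0 = time.perf_counter()

    # --- stage: data -------------------------------------------------------
    if config.dataset_dir is not None:
        samples = read_dataset(config.dataset_dir)
        manifest_data = {"source": "disk", "path": str(config.dataset_dir)}
    else:
        syn = config.synthetic or SyntheticConfig(seed=config.seed)
        samples, gen_manifest = generate_dataset(syn)
        manifest_data = {"source": "synthetic", "generator": gen_manifest}
    log.info("data: %d samples (%.1fs)", len(samples), time.perf_counter() - t0)

    scores = {t: {s.id: s.scores[t] for s in samples} for t in config.traits}
    if config.permute_labels:
        rng = np.random.default_rng(_combo_seed(config.seed, "permute"))
        ids_sorted = sorted(scores[config.traits[0]])
        for t in config.traits:
            vals = [scores[t][i] for i in ids_sorted]
            perm = rng.permutation(len(vals))
            scores[t] = {i: vals[p] for i, p in zip(ids_sorted, perm)}

    by_id = {s.id: s for s in samples}
    binlabels = {
        t: binarize_scores(scores[t], config.binarize_fraction, trait=t) for t in config.traits
    }

    # --- stage: featurize + evaluate --------------------------------------
    featurizers = {
        d: make_featurizer(
            d, variance_fraction=config.variance_fraction, hog_params=config.hog
        )
        for d in config.descriptors
    }
    cv_results: dict[tuple[str, str, str], CVResult] = {}
    for d in config.descriptors:
        td = time.perf_counter()
        for method in config.classifiers:
            for t in config.traits:
                bl = binlabels[t]
                sel = [by_id[i] for i in bl.ids]
                spec = ClassifierSpec(
                    method=method,
                    params=config.classifier_params.get(method, {}),
                    seed=_combo_seed(config.seed, d, method, t, "clf"),
                )
                res = nfold_cv(
                    sel,
                    bl.label_vector(),
                    spec,
                    n_folds=config.n_folds,
                    seed=_combo_seed(config.seed, d, method, t, "folds"),
                    level=config.level,
                    ci_multiplier=config.ci_multiplier,
                    featurizer=featurizers[d],
                    trait=t,
                    ids=bl.ids,
                )
                cv_results[(d, method, t)] = res
                log.debug(
                    "cv %s/%s/%s: %.1f%% (±%.1f)", d, method, t, res.mean_accuracy, res.ci_half_width
                )
        log.info("evaluate[%s]: done (%.1fs)", d, time.perf_counter() - td)

    accuracy_tables = {}
    for d in config.descriptors:
        table = pd.DataFrame(
            {
                t.capitalize(): [
                    _cell(cv_results[(d, m, t)].mean_accuracy, cv_results[(d, m, t)].ci_half_width)
                    for m in config.classifiers
                ]
                for t in config.traits
            },
            index=list(config.classifiers),
        )
        accuracy_tables[d] = table

    # --- stage: correlate predicted labels ---------------------------------
    corr_rows = []
    pairs = [(a, b) for i, a in enumerate(config.descriptors) for b in config.descriptors[i + 1 :]]
    for t in config.traits:
        row = {"trait": t}
        for a, b in pairs:
            pa = cv_results[(a, config.correlation_classifier, t)].predictions
            pb = cv_results[(b, config.correlation_classifier, t)].predictions
            row[f"{a}_vs_{b}"] = prediction_label_correlation(pa, pb)
        corr_rows.append(row)
    correlations = pd.DataFrame(corr_rows)

    # --- stage: point importance (geometric features vs labels) ------------
    importance: dict[str, dict] = {}
    geo_all = GeometricFeaturizer().fit(samples)
    feature_map = build_feature_map(N_POINTS)
    for t in config.traits:
        bl = binlabels[t]
        matrix = geo_all.transform([by_id[i] for i in bl.ids])
        coeffs, _ = feature_trait_correlation(matrix, bl.label_vector())
        pim = point_importance(
            coeffs,
            feature_map,
            threshold=config.importance_threshold,
            mode=config.importance_mode,
            trait=t,
            n_points=N_POINTS,
        )
        kinds = angle_vs_distance_share(
            coeffs, feature_map, threshold=config.importance_threshold, mode=config.importance_mode
        )
        importance[t] = {"map": pim, "kinds": kinds, "coefficients": coeffs}

    # --- stage: trait PCA ---------------------------------------------------
    all_traits_matrix = np.array([[s.scores[t] for t in config.traits] for s in samples])
    pca = trait_pca_projection(all_traits_matrix, trait_names=config.traits)

    # --- summary ------------------------------------------------------------
    summary_rows = []
    for t in config.traits:
        best = max(
            ((d, m, cv_results[(d, m, t)]) for d in config.descriptors for m in config.classifiers),
            key=lambda x: x[2].mean_accuracy,
        )
        learnable = any(
            cv_results[(d, m, t)].mean_accuracy - cv_results[(d, m, t)].ci_half_width > 50.0
            for d in config.descriptors
            for m in config.classifiers
        )
        summary_rows.append(
            {
                "trait": t,
                "best_descriptor": best[0],
                "best_classifier": best[1],
                "best_accuracy": best[2].mean_accuracy,
                "best_ci": best[2].ci_half_width,
                "learnable": learnable,
            }
        )
    summary = pd.DataFrame(summary_rows)

    manifest = {
        "tool": "facetraits.run_experiment",
        "seed": config.seed,
        "data": manifest_data,
        "config": _config_to_dict(config),
    }

    out_dir = Path(config.out_dir) if config.out_dir is not None else None
    result = ExperimentResult(
        config=config,
        n_samples=len(samples),
        accuracy_tables=accuracy_tables,
        cv_results=cv_results,
        correlations=correlations,
        importance=importance,
        trait_pca=pca,
        summary=summary,
        manifest=manifest,
        out_dir=out_dir,
    )
    if out_dir is not None:
        _write_outputs(result, samples, out_dir)
    log.info("experiment done (%.1fs)", time.perf_counter() - t0)
    return result


def _config_to_dict(config: ExperimentConfig) -> dict:
    d = dataclasses.asdict(config)
    d["hog"] = dataclasses.asdict(config.hog)
    if config.synthetic is not None:
        from .synthetic_faces import _config_to_dict as syn_dict

        d["synthetic"] = syn_dict(config.synthetic)
    for key in ("descriptors", "classifiers", "traits"):
        d[key] = list(d[key])
    return d


def _write_outputs(result: ExperimentResult, samples, out_dir: Path) -> None:
    import yaml

    cfg = result.config
    if out_dir.exists() and any(out_dir.iterdir()) and not cfg.overwrite:
        raise FileExistsError(f"output directory {out_dir} exists (pass overwrite)")
    out_dir.mkdir(parents=True, exist_ok=True)

    for d, table in result.accuracy_tables.items():
        table.to_csv(out_dir / f"accuracy_{d}.csv")

    long_rows = []
    pred_rows = []
    for (d, m, t), res in result.cv_results.items():
        long_rows.append(
            {
                "descriptor": d,
                "classifier": m,
                "trait": t,
                "mean_accuracy": res.mean_accuracy,
                "ci_half_width": res.ci_half_width,
                **{f"fold_{i}": a for i, a in enumerate(res.fold_accuracies)},
            }
        )
        for i, sid in enumerate(res.ids):
            pred_rows.append(
                {
                    "descriptor": d,
                    "classifier": m,
                    "trait": t,
                    "id": sid,
                    "fold": int(res.fold_assignment[i]),
                    "prediction": int(res.predictions[i]),
                    "confidence": float(res.confidences[i]),
                }
            )
    pd.DataFrame(long_rows).to_csv(out_dir / "accuracy_long.csv", index=False, float_format=CSV_FLOATS)
    pd.DataFrame(pred_rows).to_csv(out_dir / "predictions.csv", index=False, float_format=CSV_FLOATS)
    result.correlations.to_csv(out_dir / "correlations.csv", index=False, float_format=CSV_FLOATS)
    result.summary.to_csv(out_dir / "summary.csv", index=False, float_format=CSV_FLOATS)

    from .template import LANDMARK_NAMES

    mean_pts = GeometricFeaturizer().fit(samples).mean_shape_.points
    for t, entry in result.importance.items():
        pim: PointImportanceMap = entry["map"]
        pd.DataFrame(
            {
                "landmark": LANDMARK_NAMES,
                "raw_count": pim.raw_counts,
                "normalized": pim.normalized,
            }
        ).to_csv(out_dir / f"importance_{t}.csv", index=False, float_format=CSV_FLOATS)
        if cfg.write_figures:
            from .synthetic_faces import render_face

            bg = render_face(mean_pts, samples[0].image.shape)
            plot_point_importance(pim, mean_pts, background=bg, path=out_dir / f"importance_{t}.png")

    pca = result.trait_pca
    pd.DataFrame(
        pca.components[:, : min(2, pca.components.shape[1])],
        index=list(pca.trait_names),
        columns=[f"pc{i + 1}" for i in range(min(2, pca.components.shape[1]))],
    ).to_csv(out_dir / "trait_pca_components.csv", float_format=CSV_FLOATS)
    pd.DataFrame(
        {"component": np.arange(1, len(pca.variance_shares) + 1), "share": pca.variance_shares}
    ).to_csv(out_dir / "trait_pca_shares.csv", index=False, float_format=CSV_FLOATS)

    with open(out_dir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(result.manifest, fh, sort_keys=True)
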