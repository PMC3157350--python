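"""Label correlations, point-importance mapping, trait PCA, ranking."""

import numpy as np
import pytest

from facetraits.analysis import (
    angle_vs_distance_share,
    feature_trait_correlation,
    plot_point_importance,
    point_importance,
    prediction_label_correlation,
    rank_by_confidence,
    trait_pca_projection,
)
from facetraits.geometry import build_feature_map


class TestPhiCorrelation:
    def test_identical_vectors(self):
        v = np.array([1, 1, -1, -1, 1])
        assert prediction_label_correlation(v, v) == pytest.approx(1.0)

    def test_complemented_vectors(self):
        v = np.array([1, -1, 1, -1])
        assert prediction_label_correlation(v, -v) == pytest.approx(-1.0)

    def test_half_agreement_balanced(self):
        a = np.array([1, 1, -1, -1])
        b = np.array([1, -1, 1, -1])
        assert prediction_label_correlation(a, b) == pytest.approx(0.0)

    def test_constant_vector_flagged_as_zero(self):
        a = np.array([1, 1, 1, 1])
        b = np.array([1, -1, 1, -1])
        assert prediction_label_correlation(a, b) == 0.0

    def test_symmetry_and_joint_relabel_invariance(self, rng):
        a = np.where(rng.random(30) > 0.5, 1, -1)
        b = np.where(rng.random(30) > 0.5, 1, -1)
        assert prediction_label_correlation(a, b) == pytest.approx(
            prediction_label_correlation(b, a)
        )
        assert prediction_label_correlation(-a, -b) == pytest.approx(
            prediction_label_correlation(a, b)
        )

    def test_misaligned_or_invalid_inputs(self):
        with pytest.raises(ValueError):
            prediction_label_correlation([1, -1], [1, -1, 1])
        with pytest.raises(ValueError):
            prediction_label_correlation([1], [1])
        with pytest.raises(ValueError):
            prediction_label_correlation([1, 0], [1, -1])


class TestFeatureTraitCorrelation:
    def test_label_column_correlates_perfectly(self, rng):
        y = np.array([1, -1, 1, -1, 1, -1], float)
        x = np.column_stack([y, rng.normal(size=6)])
        coeffs, flags = feature_trait_correlation(x, y)
        assert coeffs[0] == pytest.approx(1.0)
        assert not flags.any()

    def test_constant_column_flagged_zero(self):
        y = np.array([1, -1, 1, -1], float)
        x = np.column_stack([np.full(4, 3.3), y])
        coeffs, flags = feature_trait_correlation(x, y)
        assert coeffs[0] == 0.0 and flags[0]
        assert coeffs[1] == pytest.approx(1.0) and not flags[1]


class TestPointImportance:
    def test_direct_counting_of_two_selected_features(self):
        fm = build_feature_map(12)
        coeffs = np.zeros(len(fm))
        for k, name in enumerate(fm.names):
            if name in ("s3_d_05_09", "s3_d_05_11"):
                coeffs[k] = 0.9
        pim = point_importance(coeffs, fm, threshold=0.5, mode="absolute", n_points=12)
        assert pim.normalized[5] == 1.0
        assert pim.normalized[9] == pytest.approx(0.5)
        assert pim.normalized[11] == pytest.approx(0.5)
        assert pim.raw_counts.sum() == 4

    def test_select_all_counts_equal_feature_multiplicity(self, rng):
        fm = build_feature_map(7)
        coeffs = rng.random(len(fm))
        pim = point_importance(coeffs, fm, threshold=0.0, mode="quantile", n_points=7)
        tally = np.zeros(7)
        for pts in fm.points:  # brute-force multiplicity tally
            for p in pts:
                tally[p] += 1
        assert np.array_equal(pim.raw_counts, tally)
        assert pim.normalized.max() == 1.0

    def test_empty_selection_warns(self):
        fm = build_feature_map(4)
        with pytest.warns(UserWarning):
            pim = point_importance(np.zeros(len(fm)), fm, threshold=0.5, mode="absolute",
                                   n_points=4)
        assert np.all(pim.normalized == 0)

    def test_reproducible_bit_exact(self, rng):
        fm = build_feature_map(9)
        coeffs = rng.normal(size=len(fm))
        a = point_importance(coeffs, fm, threshold=0.9)
        b = point_importance(coeffs, fm, threshold=0.9)
        assert np.array_equal(a.raw_counts, b.raw_counts)
        assert np.array_equal(a.selected, b.selected)


class TestAngleVsDistanceShare:
    def test_pure_distance_selection(self):
        fm = build_feature_map(6)
        coeffs = np.zeros(len(fm))
        for k, name in enumerate(fm.names):
            if name.startswith("s3_d"):
                coeffs[k] = 1.0
        out = angle_vs_distance_share(coeffs, fm, threshold=0.5, mode="absolute")
        assert out["shares"]["distance"] == 1.0
        assert out["counts"]["angle"] == out["counts"]["radius"] == 0

    def test_select_all_matches_partition(self):
        fm = build_feature_map(21)
        out = angle_vs_distance_share(np.ones(len(fm)), fm, threshold=0.0, mode="quantile")
        assert out["counts"] == {"radius": 462, "angle": 462, "distance": 210}


class TestTraitPCA:
    def test_rank_one_pair_gives_full_first_share(self, rng):
        n = 50
        latent = rng.normal(size=n)
        x = np.column_stack([latent, 2 * latent + 1, np.full(n, 4.0), np.full(n, 2.0)])
        pca = trait_pca_projection(x, trait_names=["a", "b", "c", "d"])
        assert pca.dropped == ("c", "d")
        assert pca.variance_shares[0] == pytest.approx(1.0, abs=1e-10)

    def test_variance_shares_sum_to_one(self, rng):
        x = rng.normal(size=(40, 9))
        pca = trait_pca_projection(x)
        assert pca.variance_shares.sum() == pytest.approx(1.0)

    def test_two_latent_factors_recovered(self, rng):
        """Traits built from two independent latent factors: the top-2
        eigenvalue share must come within 5 points of the planted share."""
        n, k = 400, 9
        f = rng.normal(size=(n, 2))
        loadings = rng.normal(size=(k, 2))
        noise_sd = 0.4
        x = f @ loadings.T + noise_sd * rng.normal(size=(n, k))
        signal_var = (loadings**2).sum(axis=1)
        planted_share = np.mean(signal_var / (signal_var + noise_sd**2))
        pca = trait_pca_projection(x)
        recovered = pca.variance_shares[:2].sum()
        assert recovered >= planted_share - 0.05

    def test_too_few_faces_rejected(self):
        with pytest.raises(ValueError):
            trait_pca_projection(np.ones((2, 9)))


class _FixedModel:
    def __init__(self, scores):
        self.scores = np.asarray(scores, float)

    def confidence(self, x):
        return self.scores[: len(x)]


class TestRanking:
    def test_descending_order(self):
        ranked = rank_by_confidence(_FixedModel([0.2, 0.9]), np.zeros((2, 3)), ids=["a", "b"])
        assert [r[0] for r in ranked] == ["b", "a"]

    def test_invariant_under_monotone_transform(self, rng):
        scores = rng.normal(size=12)
        base = rank_by_confidence(_FixedModel(scores), np.zeros((12, 2)))
        warped = rank_by_confidence(_FixedModel(np.exp(3 * scores)), np.zeros((12, 2)))
        assert [r[0] for r in base] == [r[0] for r in warped]

    def test_unfitted_model_raises(self):
        from facetraits.classification import KNNClassifier, NotFittedError

        with pytest.raises(NotFittedError):
            rank_by_confidence(KNNClassifier(), np.zeros((3, 2)))


def test_graded_mouth_width_gallery_ranks_by_confidence():
    """An extroversion model trained on mouth-planted scores ranks a gallery
    of faces with graded mouth widths in mouth-width order (Spearman >= 0.8)."""
    from scipy.stats import spearmanr

    from facetraits.classification import ClassifierSpec, Standardizer, binarize_scores, make_classifier
    from facetraits.descriptors import GeometricFeaturizer
    from facetraits.synthetic_faces import (
        SyntheticConfig,
        TraitSpec,
        build_shape_model,
        generate_dataset,
        render_face,
    )
    from facetraits.synthetic_faces import FaceSample
    from facetraits.template import LANDMARK_INDEX

    spec = TraitSpec("extroverted", {"mouth_width": 0.5}, intercept=-4.0, noise_sd=0.1)
    specs = tuple(
        spec if s.trait_name == "extroverted" else s
        for s in __import__("facetraits").default_trait_specs(noise_sd=0.3)
    )
    samples, _ = generate_dataset(SyntheticConfig(n_faces=80, seed=31, trait_specs=specs))
    bl = binarize_scores({s.id: s.scores["extroverted"] for s in samples}, 1 / 3)
    sel = [s for s in samples if s.id in bl.labels]
    feat = GeometricFeaturizer().fit(sel)
    scaler = Standardizer().fit(feat.transform(sel))
    clf = make_classifier(ClassifierSpec("svm_rbf", seed=0))
    clf.fit(scaler.transform(feat.transform(sel)), bl.label_vector())

    mean, _ = build_shape_model(21, 0, seed=0)
    gallery = []
    grades = np.linspace(-4.0, 4.0, 9)
    for g, delta in enumerate(grades):
        pts = mean.copy()
        pts[LANDMARK_INDEX["mouth_l"], 0] -= delta
        pts[LANDMARK_INDEX["mouth_r"], 0] += delta
        gallery.append(FaceSample(id=f"g{g}", image=render_face(pts, (64, 64)), landmarks=pts))
    ranked = rank_by_confidence(
        clf, scaler.transform(feat.transform(gallery)), ids=[s.id for s in gallery]
    )
    rank_position = {sid: pos for pos, (sid, _) in enumerate(ranked)}
    # widest mouth should rank first: positions anti-ordered with grade
    rho = spearmanr(grades, [rank_position[f"g{g}"] for g in range(9)]).statistic
    assert -rho >= 0.8


def test_plot_point_importance_writes_png(tmp_path, rng):
    fm = build_feature_map(21)
    pim = point_importance(rng.random(len(fm)), fm, threshold=0.95, n_points=21)
    from facetraits.template import template_landmarks

    out = tmp_path / "map.png"
    plot_point_importance(pim, template_landmarks((64, 64)), path=out)
    assert out.stat().st_size > 0
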