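"""Trait-judgment PCA (valence/dominance plane) and confidence ranking.

The nine trait ratings are correlated; their first two principal
components play the role of the valence and dominance dimensions of
trait-judgment space.  A trained classifier's real-valued confidence can
also rank unseen faces from least to most trait-like.
"""

import numpy as np

from facetraits import SyntheticConfig, generate_dataset, rank_by_confidence
from facetraits.analysis import trait_pca_projection
from facetraits.classification import ClassifierSpec, Standardizer, binarize_scores, make_classifier
from facetraits.descriptors import GeometricFeaturizer
from facetraits.synthetic_faces import TRAITS
from facetraits.template import structural_features

samples, _ = generate_dataset(SyntheticConfig(n_faces=150, seed=6, rater_noise_sd=0.3))
matrix = np.array([[s.scores[t] for t in TRAITS] for s in samples])
pca = trait_pca_projection(matrix, trait_names=TRAITS)
print("Trait PCA variance shares:", np.round(pca.variance_shares[:4], 3))
print(f"Top-2 components explain {100 * pca.variance_shares[:2].sum():.0f}% "
      "of the rating variance.\n")

# train an extroversion model, then rank an unseen gallery by confidence
train, gallery = samples[:120], samples[120:]
labels = binarize_scores({s.id: s.scores["extroverted"] for s in train}, 1 / 3)
selected = [s for s in train if s.id in labels.labels]
feat = GeometricFeaturizer().fit(selected)
scaler = Standardizer().fit(feat.transform(selected))
clf = make_classifier(ClassifierSpec("svm_rbf", seed=0))
clf.fit(scaler.transform(feat.transform(selected)), labels.label_vector())

ranked = rank_by_confidence(clf, scaler.transform(feat.transform(gallery)),
                            ids=[s.id for s in gallery])
widths = {s.id: structural_features(s.landmarks)["mouth_width"] for s in gallery}
print("Gallery ranked by extroversion confidence (true mouth width in px):")
for sid, conf in ranked[:8]:
    print(f"  {sid}  confidence {conf:+6.2f}   mouth width {widths[sid]:.1f}")
print()
print(
    "Confidence order tracks mouth width, the feature the trait was planted on:\n"
    "the ranking generalizes to faces the model never saw."
)
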