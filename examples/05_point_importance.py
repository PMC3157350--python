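"""Map trait-correlated geometric features back onto facial landmarks.

For a trait planted on mouth width, the features most correlated with the
binarized labels should involve the mouth corners — the point-importance
map counts, per landmark, how many of the top-correlated features touch it.
"""

import numpy as np

from facetraits import SyntheticConfig, generate_dataset
from facetraits.analysis import feature_trait_correlation, point_importance
from facetraits.classification import binarize_scores
from facetraits.descriptors import GeometricFeaturizer
from facetraits.geometry import build_feature_map
from facetraits.synthetic_faces import planted_benchmark_specs
from facetraits.template import LANDMARK_NAMES

cfg = SyntheticConfig(n_faces=150, seed=4, trait_specs=planted_benchmark_specs())
samples, _ = generate_dataset(cfg)
by_id = {s.id: s for s in samples}

labels = binarize_scores({s.id: s.scores["extroverted"] for s in samples}, 1 / 3)
selected = [by_id[i] for i in labels.ids]

featurizer = GeometricFeaturizer().fit(samples)
coeffs, _ = feature_trait_correlation(featurizer.transform(selected), labels.label_vector())
pim = point_importance(coeffs, build_feature_map(21), threshold=0.95, n_points=21)

order = np.argsort(pim.normalized)[::-1]
print("Landmark importance for the mouth-planted 'extroverted' trait (top 6):")
for i in order[:6]:
    bar = "#" * int(30 * pim.normalized[i])
    print(f"  {LANDMARK_NAMES[i]:14s} {pim.normalized[i]:5.2f} {bar}")
print()
print(
    "The mouth corners dominate: the features whose |correlation| with the\n"
    "labels is in the top 5% are concentrated on the landmarks that the trait\n"
    "was actually generated from."
)
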