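"""Cross-validate the classifier bank on one planted trait.

Ratings are binarized by keeping the top and bottom third of the ranking;
each classifier is evaluated with stratified 10-fold cross-validation and
reported as mean fold accuracy with a t-based confidence-interval
half-width.
"""

from facetraits import METHODS, SyntheticConfig, generate_dataset
from facetraits.classification import ClassifierSpec, binarize_scores, nfold_cv
from facetraits.descriptors import make_featurizer

samples, _ = generate_dataset(SyntheticConfig(n_faces=120, seed=5))
by_id = {s.id: s for s in samples}

labels = binarize_scores({s.id: s.scores["dominant"] for s in samples}, 1 / 3,
                         trait="dominant")
selected = [by_id[i] for i in labels.ids]
print(f"'dominant': {len(selected)} faces kept "
      f"({len(labels.discarded)} middle-ranked discarded)\n")

featurizer = make_featurizer("geometric")
print(f"{'classifier':14s} mean acc %  (CI)")
for method in METHODS:
    res = nfold_cv(selected, labels.label_vector(), ClassifierSpec(method, seed=1),
                   n_folds=10, seed=1, featurizer=featurizer)
    print(f"{method:14s} {res.mean_accuracy:8.1f}  (±{res.ci_half_width:.1f})")
print()
print(
    "Accuracies far above 50% show the planted structural signal (brow height,\n"
    "face width) is recoverable from landmark geometry alone; the CI half-width\n"
    "is t * s / sqrt(N) over the N=10 fold accuracies."
)
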