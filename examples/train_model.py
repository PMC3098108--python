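"""Fit scoring weights from labeled ortholog pairs.

Generates HP/MP-like pairs with the published composition shift, determines
weight signs from median relative differences, hill-climbs the magnitudes
under five-fold cross-validation, and averages fold weights into a final
model.
"""

from thermoscore import GeneratorSpec, cross_validate, finalize_model, generate_dataset

pairs = list(generate_dataset(GeneratorSpec(n_pairs=150, seed=0)).pairs)
cv = cross_validate(pairs, k=5, iterations=20_000, restarts=5, seed=0)

print(f"train accuracy  {cv.train_accuracy_mean:.3f} +/- {cv.train_accuracy_sd:.3f}")
print(f"holdout accuracy {cv.test_accuracy_mean:.3f} +/- {cv.test_accuracy_sd:.3f}")

model = finalize_model(cv.fold_results)
print("\nfinal model (fold-averaged weights):")
for name, w in zip(model.features, model.weights):
    print(f"  {name:9s} {w:+.3f}")

# Weight signs, not magnitudes, are the interpretable part: positive means
# the feature is favored in the more thermostable sequence.  Magnitudes are
# not comparable across features because the features are not on a common
# scale.
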