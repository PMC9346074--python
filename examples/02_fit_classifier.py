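"""Train the k-mer/GBDT classifier on a synthetic cohort and score held-out
samples.

Run:  python examples/02_fit_classifier.py   (~1 minute on one CPU)
"""

from motifboost import (
    AugmentationConfig,
    ModelConfig,
    MotifEffect,
    RepertoireDataset,
    SyntheticSpec,
    fit,
    generate_dataset,
    predict_scores,
    roc_auc,
)

spec = SyntheticSpec(
    n_samples=40,
    records_per_sample=400,
    motif_effect=MotifEffect("ASS", enrichment_rate_pos=0.05, enrichment_rate_neg=0.0),
    seed=11,
)
dataset = generate_dataset(spec)
train = RepertoireDataset(dataset.samples[:28], "train")
test = RepertoireDataset(dataset.samples[28:], "test")

# Small search budget keeps this example quick; drop
# enable_hyperparameter_search=False entirely for the full default pipeline.
config = ModelConfig(
    k=3,
    search_trials=5,
    cv_folds=3,
    augmentation=AugmentationConfig(copies_per_sample=2),
    seed=0,
)
model = fit(train, config)
print("chosen hyperparameters:", model.best_hyperparameters)

scores = predict_scores(model, test)
labels = [s.label_binary for s in test]
print(f"test AUC: {roc_auc(labels, [scores[s.sample_id] for s in test]):.3f}")
for sample in test.samples[:4]:
    print(f"  {sample.sample_id}  label={sample.label:8s}  "
          f"score={scores[sample.sample_id]:.3f}")
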