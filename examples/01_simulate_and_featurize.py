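"""Generate a small synthetic cohort and inspect its k-mer features.

Run:  python examples/01_simulate_and_featurize.py
"""

import numpy as np

from motifboost.kmers import kmer_index
from motifboost import (
    MotifEffect,
    SyntheticSpec,
    featurize_dataset,
    generate_dataset,
    pattern_count,
)

# 20 samples, ~300 clone records each; positives carry the motif "ASS" in
# 5% of their sequences, negatives never do.
spec = SyntheticSpec(
    n_samples=20,
    records_per_sample=300,
    motif_effect=MotifEffect("ASS", enrichment_rate_pos=0.05, enrichment_rate_neg=0.0),
    seed=7,
)
dataset = generate_dataset(spec)

sample = dataset.samples[0]
print(f"{len(dataset)} samples; first: {sample.sample_id} "
      f"({sample.n_unique} clones, {sample.total_count} reads, {sample.label})")

# 3-mer features over the 21-letter alphabet (20 amino acids + edge symbol).
features = featurize_dataset(dataset, k=3)
print(f"feature matrix: {features.matrix.shape} "
      f"(expected width {pattern_count(3)})")
print(f"rows sum to 1: {np.allclose(features.matrix.sum(axis=1), 1.0)}")

# The planted motif shows up directly in its feature column.
col = features.matrix[:, kmer_index("ASS")]
labels = features.labels
print(f"mean ASS frequency — positives: {col[labels == 1].mean():.5f}, "
      f"negatives: {col[labels == 0].mean():.5f}")
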