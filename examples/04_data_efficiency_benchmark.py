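"""Compare how the burden test and the k-mer classifier degrade as the
training cohort shrinks.

Run:  python examples/04_data_efficiency_benchmark.py   (~2-3 minutes)
"""

from motifboost import (
    AugmentationConfig,
    BurdenMethod,
    ModelConfig,
    MotifBoostMethod,
    PublicCloneEffect,
    RepertoireDataset,
    SyntheticSpec,
    generate_dataset,
    run_benchmark,
)

spec = SyntheticSpec(
    n_samples=80,
    records_per_sample=300,
    public_clone_effect=PublicCloneEffect(50, 0.8, 0.05),
    seed=5,
)
dataset = generate_dataset(spec)
pool = RepertoireDataset(dataset.samples[:60], "pool")
test = RepertoireDataset(dataset.samples[60:], "test")

methods = [
    BurdenMethod(cv_folds=3),
    MotifBoostMethod(
        ModelConfig(
            enable_hyperparameter_search=False,
            augmentation=AugmentationConfig(copies_per_sample=2),
        )
    ),
]

report = run_benchmark(
    methods, pool, test, sizes=[15, 60], trials_per_size=3, seed=0
)
print(report.summary().to_string())

# report.plot("benchmark.png") renders the distributions as box plots.
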