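import numpy as np
import pytest
from hypothesis import settings

from motifboost.repertoire import RepertoireDataset, RepertoireSample

# Property-based tests run derandomized so the suite is fully reproducible.
settings.register_profile("deterministic", derandomize=True, print_blob=False)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_sample():
    return RepertoireSample.create(
        "s1", ["CASS", "CAR"], [3, 1], label="positive", cohort="A"
    )


def make_sample(sample_id, seq_counts, label=None, cohort=None):
    seqs, counts = zip(*seq_counts.items())
    return RepertoireSample.create(
        sample_id, list(seqs), list(counts), label=label, cohort=cohort
    )


@pytest.fixture
def toy_dataset():
    """Six labeled samples with a sequence ('CAW') perfectly tracking the
    positive label and one ubiquitous sequence ('CASS')."""
    samples = [
        make_sample("p1", {"CASS": 5, "CAW": 2, "CAY": 1}, label="positive", cohort="A"),
        make_sample("p2", {"CASS": 3, "CAW": 1, "CGG": 2}, label="positive", cohort="A"),
        make_sample("p3", {"CASS": 4, "CAW": 3, "CLL": 1}, label="positive", cohort="A"),
        make_sample("n1", {"CASS": 6, "CDD": 2}, label="negative", cohort="A"),
        make_sample("n2", {"CASS": 2, "CEE": 1}, label="negative", cohort="B"),
        make_sample("n3", {"CASS": 3, "CFF": 4}, label="negative", cohort="B"),
    ]
    return RepertoireDataset(samples, name="toy")


def random_sample(rng, sample_id="r", n_seq=20, max_len=12, max_count=9, label=None):
    from motifboost.repertoire import AMINO_ACIDS

    seqs = []
    for _ in range(n_seq):
        length = int(rng.integers(1, max_len + 1))
        seqs.append("".join(rng.choice(list(AMINO_ACIDS), size=length)))
    counts = rng.integers(1, max_count + 1, size=n_seq)
    return RepertoireSample.create(sample_id, seqs, counts, label=label)
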