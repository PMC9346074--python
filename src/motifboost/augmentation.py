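"""Resampling-based data augmentation for repertoire samples.

An observed repertoire is itself a finite sample from the subject's in vivo
TCR distribution.  Redrawing read records from the observed sample (with
replacement, with probability proportional to clone count) simulates that
sampling process and yields pseudo training samples.  By default each
augmented sample contains half the read records of its source, and five
augmented copies are created per training sample.  Augmentation is applied
to training data only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .repertoire import RepertoireDataset, RepertoireSample


@dataclass(frozen=True)
class AugmentationConfig:
    """Parameters of count-weighted resampling augmentation.

    fraction
        Size of each augmented sample as a fraction of the source's total
        read-record count (clone-count mass).  Default 0.5.
    copies_per_sample
        Number of augmented copies generated per source sample.  Default 5.
    """

    fraction: float = 0.5
    copies_per_sample: int = 5

    def __post_init__(self) -> None:
        if not 0 < self.fraction <= 1:
            raise ValueError(f"fraction must be in (0, 1], got {self.fraction}")
        if self.copies_per_sample < 0:
            raise ValueError("copies_per_sample must be >= 0")


def augment_sample(
    sample: RepertoireSample,
    fraction: float,
    rng: np.random.Generator,
    sample_id: str | None = None,
) -> RepertoireSample:
    """Draw ``floor(fraction * total_count)`` read records i.i.d. with
    replacement, weighted by clone count, and merge them into a new sample.

    Label and cohort are inherited; the drawn sample's sequence set is a
    subset of the source's.
    """
    n_draw = int(np.floor(fraction * sample.total_count))
    if n_draw < 1:
        raise ValueError(
            f"fraction {fraction} of sample {sample.sample_id!r} "
            f"({sample.total_count} records) rounds to zero records"
        )
    probs = sample.counts / sample.total_count
    drawn = rng.multinomial(n_draw, probs)
    keep = drawn > 0
    new = sample.with_records(
        [s for s, k in zip(sample.sequences, keep) if k], drawn[keep]
    )
    if sample_id is not None:
        new = new.with_id(sample_id)
    return new


def augment_dataset(
    dataset: RepertoireDataset,
    config: AugmentationConfig,
    seed: int,
) -> tuple[RepertoireDataset, dict[str, str]]:
    """Originals plus ``copies_per_sample`` augmented copies per sample.

    Returns the enlarged dataset and a map from every sample id (original
    and derived) to its source id.  Downstream cross-validation must keep a
    source and its copies in the same fold to avoid leakage.
    """
    rng = np.random.default_rng(seed)
    out: list[RepertoireSample] = []
    groups: dict[str, str] = {}
    for sample in dataset:
        out.append(sample)
        groups[sample.sample_id] = sample.sample_id
        for i in range(config.copies_per_sample):
            derived_id = f"{sample.sample_id}__aug{i}"
            out.append(
                augment_sample(sample, config.fraction, rng, sample_id=derived_id)
            )
            groups[derived_id] = sample.sample_id
    return (
        RepertoireDataset(out, name=f"{dataset.name}/augmented"),
        groups,
    )
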