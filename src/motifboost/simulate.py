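"""Synthetic repertoire generator with plantable label signal.

Two independent, biologically motivated signal channels can be planted on
top of an i.i.d. random background:

* **Public clones** — a fixed set of CDR3 sequences shared across subjects,
  present in each sample with a class-dependent probability.  This is the
  whole-sequence-identity signal that the burden test exploits.
* **A 3-mer motif** — a class-dependent fraction of each sample's sequence
  records is rewritten to contain a short motif at a random position.  This
  is the sub-sequence signal that k-mer featurization exploits.

Clone counts follow a capped Zipf law to emulate the heavy-tailed clone-size
distributions of real repertoires.  Everything is driven by a single seed.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .io import write_dataset as _write_dataset
from .repertoire import (
    AMINO_ACIDS,
    LABEL_NEGATIVE,
    LABEL_POSITIVE,
    RepertoireDataset,
    RepertoireSample,
)

_AA_ARRAY = np.frombuffer(AMINO_ACIDS.encode("ascii"), dtype=np.uint8)


@dataclass(frozen=True)
class LengthLaw:
    """Discrete uniform CDR3 length distribution (inclusive bounds)."""

    minimum: int = 8
    maximum: int = 20

    def __post_init__(self) -> None:
        if not 1 <= self.minimum <= self.maximum:
            raise ValueError("invalid length bounds")

    def draw(self, rng: np.random.Generator, size: int) -> np.ndarray:
        return rng.integers(self.minimum, self.maximum + 1, size=size)


@dataclass(frozen=True)
class CloneCountLaw:
    """Heavy-tailed clone counts: Zipf with the given exponent, capped."""

    exponent: float = 1.5
    cap: int = 10_000

    def draw(self, rng: np.random.Generator, size: int) -> np.ndarray:
        return np.minimum(rng.zipf(self.exponent, size=size), self.cap)


@dataclass(frozen=True)
class PublicCloneEffect:
    """Planted public clones with class-dependent presence probabilities."""

    n_public_sequences: int = 50
    presence_prob_pos: float = 0.8
    presence_prob_neg: float = 0.05

    def __post_init__(self) -> None:
        for p in (self.presence_prob_pos, self.presence_prob_neg):
            if not 0 <= p <= 1:
                raise ValueError("presence probabilities must be in [0, 1]")


@dataclass(frozen=True)
class MotifEffect:
    """Class-dependent fraction of records rewritten to contain a motif."""

    motif: str = "ASS"
    enrichment_rate_pos: float = 0.02
    enrichment_rate_neg: float = 0.0

    def __post_init__(self) -> None:
        for r in (self.enrichment_rate_pos, self.enrichment_rate_neg):
            if not 0 <= r <= 1:
                raise ValueError("enrichment rates must be in [0, 1]")


@dataclass(frozen=True)
class SyntheticSpec:
    """Generative parameters of a labeled synthetic repertoire dataset.

    ``records_per_sample`` counts distinct background clones (table rows);
    each row additionally carries a Zipf clone count.
    """

    n_samples: int = 100
    positive_fraction: float = 0.5
    records_per_sample: int = 2_000
    length_law: LengthLaw = field(default_factory=LengthLaw)
    clone_count_law: CloneCountLaw = field(default_factory=CloneCountLaw)
    public_clone_effect: PublicCloneEffect | None = None
    motif_effect: MotifEffect | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.records_per_sample < 1:
            raise ValueError("n_samples and records_per_sample must be >= 1")
        if not 0 <= self.positive_fraction <= 1:
            raise ValueError("positive_fraction must be in [0, 1]")

    def to_dict(self) -> dict:
        out = asdict(self)
        out["length_law"] = asdict(self.length_law)
        out["clone_count_law"] = asdict(self.clone_count_law)
        if self.public_clone_effect is not None:
            out["public_clone_effect"] = asdict(self.public_clone_effect)
        if self.motif_effect is not None:
            out["motif_effect"] = asdict(self.motif_effect)
        return out

    @staticmethod
    def from_dict(data: dict) -> "SyntheticSpec":
        data = dict(data)
        if data.get("length_law"):
            data["length_law"] = LengthLaw(**data["length_law"])
        if data.get("clone_count_law"):
            data["clone_count_law"] = CloneCountLaw(**data["clone_count_law"])
        if data.get("public_clone_effect"):
            data["public_clone_effect"] = PublicCloneEffect(**data["public_clone_effect"])
        if data.get("motif_effect"):
            data["motif_effect"] = MotifEffect(**data["motif_effect"])
        return SyntheticSpec(**data)


def generate_sequence(rng: np.random.Generator, length_law: LengthLaw) -> str:
    """One CDR3 string: i.i.d. uniform letters, length from the length law."""
    length = int(length_law.draw(rng, 1)[0])
    letters = _AA_ARRAY[rng.integers(0, len(_AA_ARRAY), size=length)]
    return letters.tobytes().decode("ascii")


def _generate_sequences(
    rng: np.random.Generator, length_law: LengthLaw, n: int
) -> list[str]:
    lengths = length_law.draw(rng, n)
    letters = _AA_ARRAY[rng.integers(0, len(_AA_ARRAY), size=int(lengths.sum()))]
    out, pos = [], 0
    for ln in lengths:
        out.append(letters[pos : pos + ln].tobytes().decode("ascii"))
        pos += ln
    return out


def _embed_motif(sequence: str, motif: str, rng: np.random.Generator) -> str:
    if len(motif) > len(sequence):
        return motif  # degenerate: record shorter than the motif
    start = int(rng.integers(0, len(sequence) - len(motif) + 1))
    return sequence[:start] + motif + sequence[start + len(motif):]


def generate_dataset(spec: SyntheticSpec) -> RepertoireDataset:
    """Generate a labeled dataset according to the spec, fully seeded."""
    if spec.motif_effect is not None and len(spec.motif_effect.motif) != 3:
        warnings.warn(
            f"motif {spec.motif_effect.motif!r} is not a 3-mer; k=3 features "
            "will spread it over multiple dimensions",
            stacklevel=2,
        )
    rng = np.random.default_rng(spec.seed)

    public_sequences: list[str] = []
    if spec.public_clone_effect is not None:
        public_sequences = _generate_sequences(
            rng, spec.length_law, spec.public_clone_effect.n_public_sequences
        )

    n_pos = int(np.floor(spec.n_samples * spec.positive_fraction + 0.5))
    labels = np.array(
        [LABEL_POSITIVE] * n_pos + [LABEL_NEGATIVE] * (spec.n_samples - n_pos)
    )
    labels = labels[rng.permutation(spec.n_samples)]

    width = len(str(max(spec.n_samples - 1, 1)))
    samples = []
    for i, label in enumerate(labels):
        positive = label == LABEL_POSITIVE
        sequences = _generate_sequences(rng, spec.length_law, spec.records_per_sample)

        if spec.motif_effect is not None:
            rate = (
                spec.motif_effect.enrichment_rate_pos
                if positive
                else spec.motif_effect.enrichment_rate_neg
            )
            n_rewrite = int(np.floor(rate * spec.records_per_sample + 0.5))
            if n_rewrite > 0:
                chosen = rng.choice(spec.records_per_sample, size=n_rewrite, replace=False)
                for j in chosen:
                    sequences[j] = _embed_motif(
                        sequences[j], spec.motif_effect.motif, rng
                    )

        counts = spec.clone_count_law.draw(rng, len(sequences))

        if public_sequences:
            prob = (
                spec.public_clone_effect.presence_prob_pos
                if positive
                else spec.public_clone_effect.presence_prob_neg
            )
            present = rng.random(len(public_sequences)) < prob
            extra = [s for s, keep in zip(public_sequences, present) if keep]
            if extra:
                extra_counts = spec.clone_count_law.draw(rng, len(extra))
                sequences = sequences + extra
                counts = np.concatenate([counts, extra_counts])

        samples.append(
            RepertoireSample.create(
                f"synth_{i:0{width}d}",
                sequences,
                counts,
                label=label,
                cohort="synthetic",
                validate_alphabet=False,
            )
        )
    return RepertoireDataset(samples, name=f"synthetic(seed={spec.seed})")


def write_dataset(dataset: RepertoireDataset, out_dir: str | Path) -> None:
    """Write the dataset as minimal TSVs plus metadata (round-trips through
    :func:`motifboost.io.load_dataset`)."""
    _write_dataset(dataset, out_dir)
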