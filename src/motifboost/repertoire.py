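"""Domain containers for immune repertoires.

A repertoire is the multiset of CDR3 amino-acid sequences observed in one
subject's sample, each with a clone count (number of reads/templates
supporting that sequence).  Samples carry an optional binary infection label
and a cohort tag; a dataset is an ordered collection of samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: The 20 standard amino acids, the only letters allowed in a CDR3 string.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)

LABEL_POSITIVE = "positive"
LABEL_NEGATIVE = "negative"
LABEL_UNKNOWN = "unknown"
_VALID_LABELS = {LABEL_POSITIVE, LABEL_NEGATIVE, LABEL_UNKNOWN, None}


class RepertoireError(ValueError):
    """Base class for repertoire validation problems."""


class EmptySampleError(RepertoireError):
    """A sample contains no valid sequence records."""


def is_valid_cdr3(sequence: str) -> bool:
    """True if ``sequence`` is non-empty and uses only the 20 standard letters."""
    return bool(sequence) and all(ch in _AA_SET for ch in sequence)


@dataclass(frozen=True)
class RepertoireSample:
    """One subject's repertoire: unique CDR3 sequences with clone counts.

    Instances are canonical: sequences are unique, lexicographically sorted,
    and counts are positive integers aligned by index.  Build instances with
    :meth:`create`, which merges duplicates and sorts.
    """

    sample_id: str
    sequences: tuple[str, ...]
    counts: np.ndarray  # int64, aligned with sequences
    label: str | None = None
    cohort: str | None = None
    dropped_records: int = 0  # rows removed by sequence validation on read

    def __post_init__(self) -> None:
        if len(self.sequences) != len(self.counts):
            raise RepertoireError(
                f"sample {self.sample_id!r}: {len(self.sequences)} sequences "
                f"but {len(self.counts)} counts"
            )
        if len(self.sequences) == 0:
            raise EmptySampleError(f"sample {self.sample_id!r} has no sequences")
        if self.label not in _VALID_LABELS:
            raise RepertoireError(
                f"sample {self.sample_id!r}: invalid label {self.label!r}"
            )
        if np.any(self.counts < 1):
            raise RepertoireError(f"sample {self.sample_id!r}: counts must be >= 1")

    @classmethod
    def create(
        cls,
        sample_id: str,
        sequences,
        counts,
        label: str | None = None,
        cohort: str | None = None,
        validate_alphabet: bool = True,
        dropped_records: int = 0,
    ) -> "RepertoireSample":
        """Build a canonical sample: merge duplicate sequences (summing their
        counts), sort lexicographically, and optionally drop sequences with
        non-standard letters (counted in ``dropped_records``)."""
        merged: dict[str, int] = {}
        n_dropped = dropped_records
        for seq, cnt in zip(sequences, counts, strict=True):
            cnt = int(cnt)
            if cnt < 1:
                n_dropped += 1
                continue
            if validate_alphabet and not is_valid_cdr3(seq):
                n_dropped += 1
                continue
            merged[seq] = merged.get(seq, 0) + cnt
        if not merged:
            raise EmptySampleError(
                f"sample {sample_id!r} has no valid sequence records"
            )
        ordered = sorted(merged)
        arr = np.array([merged[s] for s in ordered], dtype=np.int64)
        return cls(
            sample_id=sample_id,
            sequences=tuple(ordered),
            counts=arr,
            label=label,
            cohort=cohort,
            dropped_records=n_dropped,
        )

    @property
    def n_unique(self) -> int:
        """Number of unique CDR3 sequences (table rows)."""
        return len(self.sequences)

    @property
    def total_count(self) -> int:
        """Total clone-count mass (number of read records)."""
        return int(self.counts.sum())

    @property
    def is_labeled(self) -> bool:
        return self.label in (LABEL_POSITIVE, LABEL_NEGATIVE)

    @property
    def label_binary(self) -> int | None:
        """1 for positive, 0 for negative, None otherwise."""
        if self.label == LABEL_POSITIVE:
            return 1
        if self.label == LABEL_NEGATIVE:
            return 0
        return None

    def with_records(self, sequences, counts) -> "RepertoireSample":
        """Same sample identity/label/cohort with replaced records."""
        return RepertoireSample.create(
            self.sample_id,
            sequences,
            counts,
            label=self.label,
            cohort=self.cohort,
            validate_alphabet=False,
        )

    def with_id(self, sample_id: str) -> "RepertoireSample":
        return replace(self, sample_id=sample_id)

    def __eq__(self, other) -> bool:
        if not isinstance(other, RepertoireSample):
            return NotImplemented
        return (
            self.sample_id == other.sample_id
            and self.sequences == other.sequences
            and np.array_equal(self.counts, other.counts)
            and self.label == other.label
            and self.cohort == other.cohort
        )

    __hash__ = None  # mutable ndarray field


@dataclass
class RepertoireDataset:
    """An ordered collection of repertoire samples with unique ids."""

    samples: list[RepertoireSample] = field(default_factory=list)
    name: str = "dataset"

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise RepertoireError(f"duplicate sample ids: {dupes}")

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self):
        return iter(self.samples)

    def __getitem__(self, sample_id: str) -> RepertoireSample:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(sample_id)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def labeled(self, name: str | None = None) -> "RepertoireDataset":
        """Subset of samples with a definite positive/negative label."""
        return RepertoireDataset(
            [s for s in self.samples if s.is_labeled],
            name=name or f"{self.name}/labeled",
        )

    def unlabeled(self) -> "RepertoireDataset":
        return RepertoireDataset(
            [s for s in self.samples if not s.is_labeled],
            name=f"{self.name}/unlabeled",
        )

    @property
    def labels(self) -> np.ndarray:
        """Binary labels of the labeled subset, in sample order."""
        return np.array(
            [s.label_binary for s in self.samples if s.is_labeled], dtype=np.int64
        )

    @property
    def positive_fraction(self) -> float:
        labs = self.labels
        if labs.size == 0:
            raise RepertoireError(f"dataset {self.name!r} has no labeled samples")
        return float(labs.mean())

    @property
    def cohorts(self) -> set[str]:
        return {s.cohort for s in self.samples if s.cohort is not None}

    def subset(self, sample_ids, name: str | None = None) -> "RepertoireDataset":
        wanted = set(sample_ids)
        return RepertoireDataset(
            [s for s in self.samples if s.sample_id in wanted],
            name=name or self.name,
        )
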