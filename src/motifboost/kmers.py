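"""k-mer abundance featurization of repertoires.

Each repertoire is summarized by the multinomial distribution of its k-mer
abundances.  Sequences are padded with a single edge symbol ``#`` at both
ends so that terminal motifs are distinguishable, giving an effective
alphabet of 21 letters; for the default k=3 the feature vector has
21**3 = 9,261 dimensions, indexed lexicographically (``#`` sorts before the
amino acids).  Each k-mer occurrence is weighted either by the clone count
of its source sequence (``clone_count``, the default, which uses abundance
information) or by 1 (``unique``); the vector is normalized to sum to one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .repertoire import AMINO_ACIDS, RepertoireDataset, RepertoireSample

EDGE_SYMBOL = "#"
#: Feature alphabet in index order; '#' sorts before every amino acid.
FEATURE_ALPHABET = EDGE_SYMBOL + AMINO_ACIDS
ALPHABET_SIZE = len(FEATURE_ALPHABET)  # 21

WEIGHTINGS = ("clone_count", "unique")

_CHAR_CODES = np.full(128, -1, dtype=np.int64)
for _i, _ch in enumerate(FEATURE_ALPHABET):
    _CHAR_CODES[ord(_ch)] = _i


def pattern_count(k: int, include_edge: bool = True) -> int:
    """Number of k-mer patterns: (21)**k with the edge symbol, 20**k without.

    For k=3 with the edge symbol this is 9,261 (the feature dimension);
    for k=4 over the plain 20-letter alphabet it is 160,000.
    """
    base = ALPHABET_SIZE if include_edge else len(AMINO_ACIDS)
    return base**k


def kmer_index(kmer: str) -> int:
    """Lexicographic index of a k-mer over the 21-letter feature alphabet."""
    idx = 0
    for ch in kmer:
        code = _CHAR_CODES[ord(ch)] if ord(ch) < 128 else -1
        if code < 0:
            raise ValueError(f"character {ch!r} not in feature alphabet")
        idx = idx * ALPHABET_SIZE + code
    return idx


def kmer_string(index: int, k: int) -> str:
    """Inverse of :func:`kmer_index`."""
    if not 0 <= index < ALPHABET_SIZE**k:
        raise ValueError(f"index {index} out of range for k={k}")
    chars = []
    for _ in range(k):
        index, rem = divmod(index, ALPHABET_SIZE)
        chars.append(FEATURE_ALPHABET[rem])
    return "".join(reversed(chars))


def enumerate_kmers(sequence: str, k: int) -> list[str]:
    """All width-k windows over the edge-padded sequence ``# + seq + #``.

    A sequence of length L yields L + 2 - k + 1 windows; for k=3 that is
    exactly L windows.
    """
    if not sequence:
        raise ValueError("cannot enumerate k-mers of an empty sequence")
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    padded = EDGE_SYMBOL + sequence + EDGE_SYMBOL
    if k > len(padded):
        raise ValueError(
            f"k={k} exceeds padded sequence length {len(padded)}"
        )
    return [padded[i : i + k] for i in range(len(padded) - k + 1)]


@dataclass(frozen=True)
class KmerFeatureVector:
    """A sample's normalized k-mer abundance distribution."""

    k: int
    weighting: str
    values: np.ndarray  # dense, length ALPHABET_SIZE**k, sums to 1

    def __post_init__(self) -> None:
        expected = pattern_count(self.k)
        if len(self.values) != expected:
            raise ValueError(
                f"feature vector length {len(self.values)} != {expected}"
            )


@dataclass
class FeatureMatrix:
    """Stacked feature vectors for a dataset (rows follow dataset order)."""

    sample_ids: list[str]
    matrix: np.ndarray  # (n_samples, ALPHABET_SIZE**k)
    labels: np.ndarray | None  # aligned binary labels, or None
    k: int
    weighting: str

    def __post_init__(self) -> None:
        if self.matrix.shape[0] != len(self.sample_ids):
            raise ValueError("row count does not match sample_ids")
        if self.labels is not None and len(self.labels) != len(self.sample_ids):
            raise ValueError("labels do not align with sample_ids")

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]

    def to_frame(self):
        import pandas as pd

        columns = [kmer_string(i, self.k) for i in range(self.n_features)]
        return pd.DataFrame(self.matrix, index=self.sample_ids, columns=columns)


def _encode_sample(sample: RepertoireSample) -> tuple[np.ndarray, np.ndarray]:
    """Concatenate all padded sequences into one code array.

    Returns (codes, lengths) where lengths are padded sequence lengths.
    """
    joined = EDGE_SYMBOL + (EDGE_SYMBOL + EDGE_SYMBOL).join(sample.sequences) + EDGE_SYMBOL
    raw = np.frombuffer(joined.encode("ascii"), dtype=np.uint8)
    codes = _CHAR_CODES[raw]
    if np.any(codes < 0):
        bad = joined[int(np.argmin(codes))]
        raise ValueError(f"invalid character {bad!r} in sample {sample.sample_id!r}")
    lengths = np.array([len(s) + 2 for s in sample.sequences], dtype=np.int64)
    return codes, lengths


def featurize_sample(
    sample: RepertoireSample, k: int = 3, weighting: str = "clone_count"
) -> KmerFeatureVector:
    """Compute the normalized k-mer abundance distribution of one sample."""
    if weighting not in WEIGHTINGS:
        raise ValueError(f"weighting must be one of {WEIGHTINGS}")
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    codes, lengths = _encode_sample(sample)
    # NOTE: consecutive padded sequences share no windows because each ends
    # and begins with '#': windows crossing a boundary are masked below.
    n_windows_total = len(codes) - k + 1
    if n_windows_total <= 0 or np.any(lengths < k):
        raise ValueError(
            f"k={k} exceeds a padded sequence length in sample {sample.sample_id!r}"
        )
    window_codes = np.zeros(n_windows_total, dtype=np.int64)
    for offset in range(k):
        window_codes = window_codes * ALPHABET_SIZE + codes[offset : offset + n_windows_total]

    # valid windows start within [start_i, start_i + len_i - k] of each sequence
    starts = np.concatenate(([0], np.cumsum(lengths)[:-1]))
    valid = np.zeros(n_windows_total + 1, dtype=np.int64)
    np.add.at(valid, starts, 1)
    ends = starts + lengths - k + 1
    np.add.at(valid, ends, -1)
    valid_mask = np.cumsum(valid[:-1]) > 0

    if weighting == "clone_count":
        seq_weights = sample.counts.astype(np.float64)
    else:
        seq_weights = np.ones(len(sample.sequences), dtype=np.float64)
    window_weights = np.repeat(seq_weights, lengths - k + 1)

    values = np.bincount(
        window_codes[valid_mask],
        weights=window_weights,
        minlength=pattern_count(k),
    )
    total = values.sum()
    if total <= 0:
        raise ValueError(f"sample {sample.sample_id!r} produced no k-mer windows")
    values /= total
    return KmerFeatureVector(k=k, weighting=weighting, values=values)


def featurize_dataset(
    dataset: RepertoireDataset, k: int = 3, weighting: str = "clone_count"
) -> FeatureMatrix:
    """Featurize every sample; rows follow dataset order, deterministically."""
    rows = []
    for sample in dataset:
        try:
            rows.append(featurize_sample(sample, k=k, weighting=weighting).values)
        except ValueError as exc:
            raise ValueError(f"sample {sample.sample_id!r}: {exc}") from exc
    if not rows:
        matrix = np.zeros((0, pattern_count(k)))
    else:
        matrix = np.vstack(rows)
    labels_list = [s.label_binary for s in dataset]
    labels = (
        np.array(labels_list, dtype=np.int64)
        if all(l is not None for l in labels_list) and labels_list
        else None
    )
    return FeatureMatrix(
        sample_ids=dataset.sample_ids,
        matrix=matrix,
        labels=labels,
        k=k,
        weighting=weighting,
    )
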