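"""Reading and writing per-sample repertoire tables and dataset metadata.

Two tab-separated dialects are supported:

* ``airr`` — AIRR rearrangement-style tables with a ``junction_aa`` column
  (fallback ``cdr3_amino_acid``) and a ``duplicate_count`` column (fallback
  ``templates``), covering both AIRR-C standard and ImmunoSEQ-style exports.
* ``minimal`` — exactly two columns, ``sequence`` and ``count``.

Dataset metadata is a TSV with columns ``sample_id``, ``label``, ``cohort``;
labels are ``positive`` / ``negative`` / ``unknown``.  Unknown-label samples
are loaded but excluded from training and evaluation by default.
"""

from __future__ import annotations

import os
from pathlib import Path

import pandas as pd

from .repertoire import (
    LABEL_NEGATIVE,
    LABEL_POSITIVE,
    LABEL_UNKNOWN,
    RepertoireDataset,
    RepertoireError,
    RepertoireSample,
)


class FormatError(RepertoireError):
    """A file does not conform to the expected dialect."""


class MissingFileError(RepertoireError):
    """Metadata references sample files that do not exist."""

    def __init__(self, missing_ids):
        self.missing_ids = list(missing_ids)
        super().__init__(f"no repertoire file for sample ids: {self.missing_ids}")


class CohortError(RepertoireError):
    """Invalid cohort split request."""


_AIRR_SEQ_COLUMNS = ("junction_aa", "cdr3_amino_acid")
_AIRR_COUNT_COLUMNS = ("duplicate_count", "templates")

_LABEL_ALIASES = {
    "positive": LABEL_POSITIVE,
    "+": LABEL_POSITIVE,
    "pos": LABEL_POSITIVE,
    "1": LABEL_POSITIVE,
    "true": LABEL_POSITIVE,
    "negative": LABEL_NEGATIVE,
    "-": LABEL_NEGATIVE,
    "neg": LABEL_NEGATIVE,
    "0": LABEL_NEGATIVE,
    "false": LABEL_NEGATIVE,
    "unknown": LABEL_UNKNOWN,
    "na": LABEL_UNKNOWN,
    "": LABEL_UNKNOWN,
}


def _pick_column(columns, candidates, path) -> str:
    for cand in candidates:
        if cand in columns:
            return cand
    raise FormatError(
        f"{path}: missing required column (one of {list(candidates)}); "
        f"found {list(columns)}"
    )


def read_sample_tsv(
    path: str | os.PathLike,
    dialect: str = "minimal",
    sample_id: str | None = None,
) -> RepertoireSample:
    """Read one repertoire table into a validated :class:`RepertoireSample`.

    Rows whose sequence contains characters outside the 20 standard amino
    acids (stop codons ``*``, ambiguity ``X``, lowercase, ...) or whose count
    is missing/non-positive are dropped; the number of dropped rows is kept
    on the returned sample.  Duplicate sequences are merged by summing counts.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if sample_id is None:
        sample_id = path.stem
    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if dialect == "minimal":
        seq_col = _pick_column(table.columns, ("sequence",), path)
        count_col = _pick_column(table.columns, ("count",), path)
    elif dialect == "airr":
        seq_col = _pick_column(table.columns, _AIRR_SEQ_COLUMNS, path)
        count_col = _pick_column(table.columns, _AIRR_COUNT_COLUMNS, path)
    else:
        raise ValueError(f"unknown dialect {dialect!r} (expected 'airr' or 'minimal')")

    counts = pd.to_numeric(table[count_col], errors="coerce")
    bad_count = counts.isna() | (counts < 1) | (counts != counts.round())
    n_bad = int(bad_count.sum())
    good = table.loc[~bad_count, seq_col].tolist()
    good_counts = counts[~bad_count].astype(int).tolist()
    # sequence validation (and duplicate merging) happens in create()
    return RepertoireSample.create(
        sample_id, good, good_counts, dropped_records=n_bad
    )


def write_sample_tsv(sample: RepertoireSample, path: str | os.PathLike) -> None:
    """Write a sample in the minimal dialect (columns ``sequence``, ``count``)."""
    frame = pd.DataFrame(
        {"sequence": list(sample.sequences), "count": sample.counts}
    )
    frame.to_csv(path, sep="\t", index=False)


def read_metadata(path: str | os.PathLike) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("sample_id", "label", "cohort"):
        if col not in meta.columns:
            raise FormatError(f"{path}: metadata missing required column {col!r}")
    labels = []
    for raw in meta["label"]:
        norm = _LABEL_ALIASES.get(raw.strip().lower())
        if norm is None:
            raise FormatError(f"{path}: unrecognized label {raw!r}")
        labels.append(norm)
    meta = meta.assign(label=labels)
    return meta


def load_dataset(
    sample_dir: str | os.PathLike,
    metadata_path: str | os.PathLike,
    dialect: str = "minimal",
    name: str | None = None,
) -> RepertoireDataset:
    """Load every sample listed in the metadata table.

    Samples labeled ``unknown`` are retained but flagged, so downstream
    training and evaluation (which use the labeled subset) skip them.
    """
    sample_dir = Path(sample_dir)
    meta = read_metadata(metadata_path)
    paths = {}
    missing = []
    for sid in meta["sample_id"]:
        p = sample_dir / f"{sid}.tsv"
        if p.exists():
            paths[sid] = p
        else:
            missing.append(sid)
    if missing:
        raise MissingFileError(missing)
    samples = []
    for row in meta.itertuples(index=False):
        base = read_sample_tsv(paths[row.sample_id], dialect=dialect,
                               sample_id=row.sample_id)
        samples.append(
            RepertoireSample(
                sample_id=base.sample_id,
                sequences=base.sequences,
                counts=base.counts,
                label=row.label,
                cohort=row.cohort or None,
                dropped_records=base.dropped_records,
            )
        )
    return RepertoireDataset(samples, name=name or str(sample_dir))


def write_dataset(dataset: RepertoireDataset, out_dir: str | os.PathLike) -> None:
    """Write one minimal TSV per sample plus ``metadata.tsv``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for sample in dataset:
        write_sample_tsv(sample, out_dir / f"{sample.sample_id}.tsv")
        rows.append(
            {
                "sample_id": sample.sample_id,
                "label": sample.label or LABEL_UNKNOWN,
                "cohort": sample.cohort or "",
            }
        )
    pd.DataFrame(rows).to_csv(out_dir / "metadata.tsv", sep="\t", index=False)


def split_by_cohort(
    dataset: RepertoireDataset, train_cohort: str, test_cohort: str
) -> tuple[RepertoireDataset, RepertoireDataset]:
    """Split a dataset into disjoint train/test sets by cohort tag.

    Cross-cohort evaluation reduces the chance of shortcut learning through
    facility-specific batch effects.
    """
    if train_cohort == test_cohort:
        raise CohortError("train and test cohort must differ")
    cohorts = dataset.cohorts
    for c in (train_cohort, test_cohort):
        if c not in cohorts:
            raise CohortError(f"cohort {c!r} not present (have {sorted(cohorts)})")
    train = RepertoireDataset(
        [s for s in dataset if s.cohort == train_cohort],
        name=f"{dataset.name}/{train_cohort}",
    )
    test = RepertoireDataset(
        [s for s in dataset if s.cohort == test_cohort],
        name=f"{dataset.name}/{test_cohort}",
    )
    if len(test) == 0:
        raise CohortError(f"test cohort {test_cohort!r} is empty")
    if len(train) == 0:
        raise CohortError(f"train cohort {train_cohort!r} is empty")
    return train, test
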