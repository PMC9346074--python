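"""Benchmarking utilities: ROC-AUC, stratified subsampling learning trials,
sequence-depth subsampling, axis-projection scoring of 2-D embeddings, and
prediction-profile comparison.

The data-efficiency protocol trains a method on many independent stratified
subsamples of a training cohort and scores a fixed held-out cohort, so that
the distribution of ROC-AUC over "learning trials" reveals how gracefully a
method degrades as the number of training samples shrinks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

from ._seeds import derive_seed
from .repertoire import RepertoireDataset, RepertoireSample


def roc_auc(labels, scores) -> float:
    """Area under the ROC curve; equals the pairwise-concordance statistic
    P(score_pos > score_neg) + 0.5 * P(tie)."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise ValueError("labels and scores must have equal length")
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC-AUC requires both classes")
    return float(roc_auc_score(labels, scores))


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def stratified_subsample(
    dataset: RepertoireDataset, n: int, rng: np.random.Generator
) -> RepertoireDataset:
    """Draw ``n`` labeled samples without replacement, preserving the class
    proportion as closely as possible (positives = round(n * pos_fraction),
    clamped so both classes stay non-empty)."""
    labeled = list(dataset.labeled())
    if n < 2 or n > len(labeled):
        raise ValueError(f"subsample size {n} outside [2, {len(labeled)}]")
    pos = [s for s in labeled if s.label_binary == 1]
    neg = [s for s in labeled if s.label_binary == 0]
    n_pos = _round_half_away(n * len(pos) / len(labeled))
    n_pos = min(max(n_pos, 1), n - 1)
    chosen_pos = rng.choice(len(pos), size=n_pos, replace=False)
    chosen_neg = rng.choice(len(neg), size=n - n_pos, replace=False)
    picked = [pos[i] for i in sorted(chosen_pos)] + [neg[i] for i in sorted(chosen_neg)]
    return RepertoireDataset(picked, name=f"{dataset.name}/N={n}")


def subsample_sequences(
    dataset: RepertoireDataset, ratio: float, rng: np.random.Generator
) -> RepertoireDataset:
    """Reduce each sample's sequencing depth: keep floor(ratio * total_count)
    read records drawn without replacement over records (a multivariate
    hypergeometric draw over clone counts), preserving relative clone
    frequencies in expectation."""
    if not 0 < ratio <= 1:
        raise ValueError(f"ratio must be in (0, 1], got {ratio}")
    out = []
    for sample in dataset:
        if ratio == 1.0:
            out.append(sample)
            continue
        n_keep = int(math.floor(ratio * sample.total_count))
        if n_keep < 1:
            raise ValueError(
                f"ratio {ratio} reduces sample {sample.sample_id!r} to zero records"
            )
        kept = rng.multivariate_hypergeometric(sample.counts, n_keep)
        mask = kept > 0
        out.append(
            sample.with_records(
                [s for s, m in zip(sample.sequences, mask) if m], kept[mask]
            )
        )
    return RepertoireDataset(out, name=f"{dataset.name}/depth={ratio}")


@dataclass(frozen=True)
class TrialResult:
    """Outcome of one learning trial (subsample -> fit -> test-score)."""

    method: str
    train_size: int
    trial_index: int
    seed: int
    roc_auc: float  # NaN when the method failed on this trial
    scores: dict[str, float] = field(default_factory=dict)
    error: str | None = None


@dataclass
class BenchmarkReport:
    """All trial results of a benchmark run plus summary statistics."""

    results: list[TrialResult]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "method": r.method,
                    "train_size": r.train_size,
                    "trial_index": r.trial_index,
                    "seed": r.seed,
                    "roc_auc": r.roc_auc,
                    "error": r.error or "",
                }
                for r in self.results
            ]
        )

    def summary(self) -> pd.DataFrame:
        """Median, quartiles, mean and sd of ROC-AUC per (method, N)."""
        frame = self.to_frame()
        grouped = frame.groupby(["method", "train_size"])["roc_auc"]
        out = grouped.agg(
            median="median",
            q1=lambda s: s.quantile(0.25),
            q3=lambda s: s.quantile(0.75),
            mean="mean",
            sd="std",
            n_trials="count",
        )
        return out.reset_index()

    def plot(self, path=None):
        """Box plot of ROC-AUC versus training-set size, one panel per
        method (whiskers at 1.5 IQR)."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        frame = self.to_frame().dropna(subset=["roc_auc"])
        methods = sorted(frame["method"].unique())
        fig, axes = plt.subplots(
            1, len(methods), figsize=(4 * len(methods), 3.5), squeeze=False
        )
        for ax, method in zip(axes[0], methods):
            sub = frame[frame["method"] == method]
            sizes = sorted(sub["train_size"].unique())
            data = [sub.loc[sub["train_size"] == n, "roc_auc"] for n in sizes]
            ax.boxplot(data, tick_labels=[str(n) for n in sizes], whis=1.5)
            ax.set_title(method)
            ax.set_xlabel("training samples (N)")
            ax.set_ylabel("ROC-AUC")
            ax.set_ylim(0, 1)
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=150)
            plt.close(fig)
        return fig


class BenchmarkMethod:
    """Protocol for benchmarked methods: a name and a fit-and-score call."""

    name: str = "method"

    def fit_score(
        self,
        train: RepertoireDataset,
        test: RepertoireDataset,
        seed: int,
    ) -> dict[str, float]:
        raise NotImplementedError


class MotifBoostMethod(BenchmarkMethod):
    """k-mer/GBDT classifier adapter for the benchmark loop."""

    def __init__(self, config=None, name: str = "motifboost"):
        from .model import ModelConfig

        self.config = config or ModelConfig()
        self.name = name

    def fit_score(self, train, test, seed):
        from dataclasses import replace

        from .model import fit, predict_scores

        model = fit(train, replace(self.config, seed=seed))
        return predict_scores(model, test)


class BurdenMethod(BenchmarkMethod):
    """Burden-test adapter with threshold tuning for the benchmark loop."""

    def __init__(self, grid=None, cv_folds: int = 5, name: str = "burden"):
        from .burden import DEFAULT_THRESHOLD_GRID

        self.grid = grid or DEFAULT_THRESHOLD_GRID
        self.cv_folds = cv_folds
        self.name = name

    def fit_score(self, train, test, seed):
        from .burden import predict_burden_scores, tune_threshold

        model = tune_threshold(train, self.grid, cv_folds=self.cv_folds, seed=seed)
        return predict_burden_scores(model, test)


def run_benchmark(
    methods: list[BenchmarkMethod],
    train: RepertoireDataset,
    test: RepertoireDataset,
    sizes: list[int],
    trials_per_size: int = 50,
    seed: int = 0,
) -> BenchmarkReport:
    """Run the stratified-subsampling data-efficiency benchmark.

    For every (method, N, trial) an independent stratified subsample of the
    training set is drawn, the method is fitted on it, and the fixed test
    set is scored.  Trial seeds derive deterministically from
    (seed, method name, N, trial), so the report is a pure function of its
    inputs; per-trial method failures are recorded, not fatal.
    """
    overlap = set(train.sample_ids) & set(test.sample_ids)
    if overlap:
        raise ValueError(f"train/test overlap: {sorted(overlap)[:5]}")
    test_labeled = test.labeled()
    test_labels = {s.sample_id: s.label_binary for s in test_labeled}
    results = []
    for method in methods:
        for n in sizes:
            for trial in range(trials_per_size):
                trial_seed = derive_seed(seed, method.name, n, trial)
                rng = np.random.default_rng(trial_seed)
                subsample = stratified_subsample(train, n, rng)
                try:
                    scores = method.fit_score(subsample, test_labeled, trial_seed)
                    auc = roc_auc(
                        [test_labels[sid] for sid in scores],
                        [scores[sid] for sid in scores],
                    )
                    results.append(
                        TrialResult(method.name, n, trial, trial_seed, auc, scores)
                    )
                except Exception as exc:  # noqa: BLE001 - recorded per trial
                    results.append(
                        TrialResult(
                            method.name, n, trial, trial_seed, float("nan"),
                            {}, error=str(exc),
                        )
                    )
    return BenchmarkReport(results)


def axis_projection_auc(coords, labels, axis) -> float:
    """ROC-AUC of samples projected onto an axis of a 2-D embedding.

    ``axis`` is either a slope (the line y = slope * x) or a 2-vector;
    each point's projection coordinate serves as its prediction score.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise ValueError("coords must be (n, 2)")
    if np.isscalar(axis):
        vec = np.array([1.0, float(axis)])
    else:
        vec = np.asarray(axis, dtype=float)
    norm = np.linalg.norm(vec)
    if norm == 0:
        raise ValueError("axis must be a non-zero vector")
    projections = coords @ (vec / norm)
    return roc_auc(labels, projections)


def optimize_axis_slope(
    coords, labels, n_angles: int = 360
) -> tuple[float, float]:
    """1-D search for the projection axis maximizing training ROC-AUC.

    Scans axis angles over half the circle (projection AUC at angle theta
    and theta+pi are mirror images).  Returns (best_slope, best_auc); a
    near-vertical axis maps to a large finite slope.
    """
    best_slope, best_auc = 0.0, -np.inf
    for angle in np.linspace(-np.pi / 2, np.pi / 2, n_angles, endpoint=False):
        vec = (np.cos(angle), np.sin(angle))
        if abs(vec[0]) < 1e-12:
            continue
        auc = axis_projection_auc(coords, labels, vec)
        auc = max(auc, 1 - auc)  # the opposite direction is the same axis
        if auc > best_auc:
            best_slope, best_auc = vec[1] / vec[0], auc
    return float(best_slope), float(best_auc)


def normalized_ranks(scores: dict[str, float]) -> dict[str, float]:
    """Map scores to average-rank normalized ranks in [0, 1]."""
    ids = sorted(scores)
    ranks = stats.rankdata([scores[i] for i in ids])
    n = len(ids)
    if n == 1:
        return {ids[0]: 0.5}
    return {i: float((r - 1) / (n - 1)) for i, r in zip(ids, ranks)}


def prediction_profile_correlation(
    scores_a: dict[str, float], scores_b: dict[str, float]
) -> float:
    """Spearman rank correlation between two methods' prediction profiles
    (normalized ranks over the same samples, average-rank tie handling)."""
    common = sorted(set(scores_a) & set(scores_b))
    if len(common) < 3:
        raise ValueError("need at least 3 common samples")
    a = [scores_a[i] for i in common]
    b = [scores_b[i] for i in common]
    return float(stats.spearmanr(a, b).statistic)
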