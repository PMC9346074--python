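"""Emerson-style burden test for repertoire classification.

The burden test classifies a repertoire from the whole-sequence identity of
public TCRs.  Training proceeds in three steps:

1. For every unique CDR3 in the training set, a one-sided Fisher exact test
   for enrichment of presence (membership, not clone count) in positive
   samples; sequences with p-value at or below a threshold form the
   label-associated set.
2. For each training sample the burden pair (x, n) is computed: n unique
   sequences, x of them associated.  For each class a beta-binomial model of
   x given n is fitted by Newton ascent on the log-likelihood, initialized
   at the method-of-moments estimate — making the whole procedure
   deterministic.
3. A sample is scored by the log-likelihood ratio of its burden pair under
   the positive versus the negative class model.

The p-value threshold is the only hyperparameter; it is tuned by
cross-validated ROC-AUC over a log-spaced grid.  No multiple-testing
correction is applied inside selection (the threshold itself is tuned).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .repertoire import RepertoireDataset, RepertoireSample

#: Log-spaced p-value threshold grid bracketing the published choice.
DEFAULT_THRESHOLD_GRID = (
    1e-5, 3e-5, 1e-4, 3e-4, 1e-3, 3e-3, 1e-2, 3e-2, 1e-1,
)


def fisher_exact_one_sided(a: int, b: int, c: int, d: int) -> float:
    """One-sided Fisher exact p-value for enrichment in the first row.

    The 2x2 table is ((a, b), (c, d)) = ((positives with the sequence,
    positives without), (negatives with, negatives without)); the p-value is
    the hypergeometric upper tail P[X >= a] at fixed margins.
    """
    for v in (a, b, c, d):
        if v < 0:
            raise ValueError("table entries must be non-negative")
    if a == 0:
        return 1.0  # observed count is the minimum of the tail
    total = a + b + c + d
    n_present = a + c
    n_pos = a + b
    # X ~ Hypergeom(total, n_present, n_pos); sf(a-1) = P[X >= a]
    return float(stats.hypergeom.sf(a - 1, total, n_present, n_pos))


class AssociationTable:
    """Per-sequence presence counts and Fisher p-values on a training set."""

    def __init__(self, table: pd.DataFrame, n_pos_total: int, n_neg_total: int):
        self.table = table  # index: sequence; columns: n_pos_present, n_neg_present, p_value
        self.n_pos_total = n_pos_total
        self.n_neg_total = n_neg_total

    def __len__(self) -> int:
        return len(self.table)

    @property
    def sequences(self) -> pd.Index:
        return self.table.index

    def associated_set(self, p_threshold: float) -> frozenset[str]:
        # small relative slack so thresholds expressible exactly in decimal
        # (e.g. 0.05) admit tail sums computed in binary floating point
        mask = self.table["p_value"].to_numpy() <= p_threshold * (1 + 1e-9)
        return frozenset(self.table.index[mask])

    def to_frame(self) -> pd.DataFrame:
        out = self.table.copy()
        out["n_pos_total"] = self.n_pos_total
        out["n_neg_total"] = self.n_neg_total
        return out


def build_association_table(train: RepertoireDataset) -> AssociationTable:
    """Fisher-test every unique training sequence for positive enrichment.

    Presence is membership (a sequence occurs at least once in a sample);
    clone counts are ignored.  P-values for identical 2x2 tables are
    computed once and shared.
    """
    labeled = train.labeled()
    labels = labeled.labels
    if len(labeled) == 0 or len(np.unique(labels)) < 2:
        raise ValueError("association table requires labeled samples of both classes")
    n_pos_total = int(labels.sum())
    n_neg_total = int(len(labels) - n_pos_total)

    seq_chunks, lab_chunks = [], []
    for sample in labeled:
        seq_chunks.append(np.asarray(sample.sequences, dtype=object))
        lab_chunks.append(np.full(sample.n_unique, sample.label_binary, dtype=np.int64))
    all_seqs = np.concatenate(seq_chunks)
    all_labs = np.concatenate(lab_chunks)

    uniq, inverse = np.unique(all_seqs, return_inverse=True)
    n_pos_present = np.bincount(inverse, weights=all_labs, minlength=len(uniq)).astype(np.int64)
    n_present = np.bincount(inverse, minlength=len(uniq))
    n_neg_present = (n_present - n_pos_present).astype(np.int64)

    # one Fisher computation per distinct (a, c) pair
    pair_codes = n_pos_present * (n_neg_total + 1) + n_neg_present
    distinct, pair_inverse = np.unique(pair_codes, return_inverse=True)
    da = distinct // (n_neg_total + 1)
    dc = distinct % (n_neg_total + 1)
    total = n_pos_total + n_neg_total
    p_distinct = stats.hypergeom.sf(da - 1, total, da + dc, n_pos_total)
    p_values = p_distinct[pair_inverse]

    table = pd.DataFrame(
        {
            "n_pos_present": n_pos_present,
            "n_neg_present": n_neg_present,
            "p_value": p_values,
        },
        index=pd.Index(uniq, name="sequence"),
    )
    return AssociationTable(table, n_pos_total, n_neg_total)


def compute_burden(
    sample: RepertoireSample, associated_set: frozenset[str] | set[str]
) -> tuple[int, int]:
    """Burden pair (x, n): n unique sequences, x of them label-associated."""
    n = sample.n_unique
    x = sum(1 for s in sample.sequences if s in associated_set)
    return x, n


class DegenerateBurdenError(ValueError):
    """Burden fractions have zero variance; use the binomial fallback."""


def betabinom_loglik(alpha: float, beta: float, xs: np.ndarray, ns: np.ndarray) -> float:
    """Beta-binomial log-likelihood (binomial coefficient terms included)."""
    return float(
        np.sum(
            special.gammaln(ns + 1)
            - special.gammaln(xs + 1)
            - special.gammaln(ns - xs + 1)
            + special.betaln(xs + alpha, ns - xs + beta)
            - special.betaln(alpha, beta)
        )
    )


def method_of_moments(xs: np.ndarray, ns: np.ndarray) -> tuple[float, float]:
    """Moment-matching initializer from the mean and variance of x/n."""
    fractions = xs / ns
    mu = float(fractions.mean())
    var = float(fractions.var(ddof=0))
    if var <= 0 or mu <= 0 or mu >= 1:
        raise DegenerateBurdenError(
            "zero-variance or boundary burden fractions; fit a binomial instead"
        )
    common = mu * (1 - mu) / var - 1
    if common <= 0:
        # variance exceeds the beta family's maximum; start from a diffuse prior
        common = 1e-2 / max(mu, 1 - mu)
    return mu * common, (1 - mu) * common


def fit_betabinomial(
    burdens: list[tuple[int, int]],
    tol: float = 1e-8,
    max_iter: int = 100,
) -> tuple[float, float]:
    """Maximum-likelihood (alpha, beta) by Newton ascent from the
    method-of-moments initializer.

    Newton steps are halved whenever they would leave the positive quadrant
    or decrease the log-likelihood; convergence is declared when the
    gradient norm drops below ``tol``.  The procedure is deterministic.
    """
    if len(burdens) < 2:
        raise ValueError("need at least two burden pairs")
    xs = np.array([x for x, _ in burdens], dtype=np.float64)
    ns = np.array([n for _, n in burdens], dtype=np.float64)
    if np.any(xs < 0) or np.any(xs > ns):
        raise ValueError("burden pairs must satisfy 0 <= x <= n")
    if np.all(xs == 0) or np.all(xs == ns):
        raise DegenerateBurdenError(
            "all burdens at a boundary; fit a binomial instead"
        )

    alpha, beta = method_of_moments(xs, ns)

    def grad_hess(a: float, b: float):
        ga = np.sum(special.digamma(xs + a) - special.digamma(ns + a + b)
                    - special.digamma(a) + special.digamma(a + b))
        gb = np.sum(special.digamma(ns - xs + b) - special.digamma(ns + a + b)
                    - special.digamma(b) + special.digamma(a + b))
        t_ab = np.sum(-special.polygamma(1, ns + a + b) + special.polygamma(1, a + b))
        haa = np.sum(special.polygamma(1, xs + a) - special.polygamma(1, a)) + t_ab
        hbb = np.sum(special.polygamma(1, ns - xs + b) - special.polygamma(1, b)) + t_ab
        return np.array([ga, gb]), np.array([[haa, t_ab], [t_ab, hbb]])

    ll = betabinom_loglik(alpha, beta, xs, ns)
    for _ in range(max_iter):
        grad, hess = grad_hess(alpha, beta)
        if np.linalg.norm(grad) < tol:
            break
        try:
            step = np.linalg.solve(hess, -grad)
        except np.linalg.LinAlgError:
            step = grad  # fall back to gradient ascent
        if np.dot(step, grad) <= 0:
            step = grad
        scale = 1.0
        for _ in range(60):
            na, nb = alpha + scale * step[0], beta + scale * step[1]
            if na > 0 and nb > 0:
                nll = betabinom_loglik(na, nb, xs, ns)
                if nll >= ll:
                    alpha, beta, ll = na, nb, nll
                    break
            scale *= 0.5
        else:
            break  # no improving step found
    return float(alpha), float(beta)


@dataclass(frozen=True)
class ClassModel:
    """Per-class burden distribution: beta-binomial, or binomial fallback
    when the burden fractions are degenerate."""

    kind: str  # "betabinomial" | "binomial"
    alpha: float | None = None
    beta: float | None = None
    p: float | None = None

    def logpmf(self, x: int, n: int) -> float:
        if self.kind == "betabinomial":
            return float(stats.betabinom.logpmf(x, n, self.alpha, self.beta))
        return float(stats.binom.logpmf(x, n, self.p))


def _fit_class_model(burdens: list[tuple[int, int]]) -> ClassModel:
    try:
        alpha, beta = fit_betabinomial(burdens)
        return ClassModel(kind="betabinomial", alpha=alpha, beta=beta)
    except DegenerateBurdenError:
        total_x = sum(x for x, _ in burdens)
        total_n = sum(n for _, n in burdens)
        eps = 1.0 / (2.0 * max(total_n, 1))
        p = min(max(total_x / max(total_n, 1), eps), 1 - eps)
        return ClassModel(kind="binomial", p=p)


@dataclass(frozen=True)
class BurdenModel:
    """Fitted burden classifier: associated set, threshold, class models."""

    associated_set: frozenset[str]
    p_threshold: float
    positive_model: ClassModel
    negative_model: ClassModel

    def score(self, sample: RepertoireSample) -> float:
        return score_burden(self, sample)


def score_burden(model: BurdenModel, sample: RepertoireSample) -> float:
    """Log-likelihood ratio of the sample's burden pair: positive vs
    negative class model.  Deterministic; positive means more CMV-like."""
    if model.positive_model is None or model.negative_model is None:
        raise ValueError("burden model is not fitted")
    x, n = compute_burden(sample, model.associated_set)
    return model.positive_model.logpmf(x, n) - model.negative_model.logpmf(x, n)


def fit_burden_model(
    train: RepertoireDataset,
    p_threshold: float,
    table: AssociationTable | None = None,
) -> BurdenModel:
    """Fit the burden classifier at one p-value threshold."""
    labeled = train.labeled()
    if table is None:
        table = build_association_table(labeled)
    associated = table.associated_set(p_threshold)
    pos_burdens = [
        compute_burden(s, associated) for s in labeled if s.label_binary == 1
    ]
    neg_burdens = [
        compute_burden(s, associated) for s in labeled if s.label_binary == 0
    ]
    return BurdenModel(
        associated_set=associated,
        p_threshold=p_threshold,
        positive_model=_fit_class_model(pos_burdens),
        negative_model=_fit_class_model(neg_burdens),
    )


def predict_burden_scores(
    model: BurdenModel, dataset: RepertoireDataset
) -> dict[str, float]:
    return {s.sample_id: score_burden(model, s) for s in dataset}


def tune_threshold(
    train: RepertoireDataset,
    grid=DEFAULT_THRESHOLD_GRID,
    cv_folds: int = 5,
    seed: int = 0,
) -> BurdenModel:
    """Select the p-value threshold by cross-validated ROC-AUC and refit.

    For each fold the association table is built on the fold-train samples
    once and every threshold is evaluated against it.  A threshold whose
    associated set is empty on a fold contributes a chance-level 0.5 for
    that fold; if every threshold yields an empty set on every fold, the
    grid is unusable and an error is raised.  Ties are broken toward the
    smallest threshold.
    """
    grid = sorted(grid)
    if not grid:
        raise ValueError("threshold grid must be non-empty")
    labeled = train.labeled()
    labels = labeled.labels
    if len(np.unique(labels)) < 2:
        raise ValueError("threshold tuning requires both classes")
    samples = list(labeled)

    splitter = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    fold_aucs = {t: [] for t in grid}
    any_nonempty = {t: False for t in grid}
    for train_idx, val_idx in splitter.split(np.zeros_like(labels), labels):
        fold_train = RepertoireDataset([samples[i] for i in train_idx], name="cv-train")
        fold_val = [samples[i] for i in val_idx]
        val_labels = np.array([s.label_binary for s in fold_val])
        table = build_association_table(fold_train)
        for t in grid:
            associated = table.associated_set(t)
            if not associated:
                fold_aucs[t].append(0.5)
                continue
            any_nonempty[t] = True
            sub_model = fit_burden_model(fold_train, t, table=table)
            val_scores = [score_burden(sub_model, s) for s in fold_val]
            if len(np.unique(val_labels)) < 2:
                fold_aucs[t].append(0.5)
            else:
                fold_aucs[t].append(roc_auc_score(val_labels, val_scores))
    if not any(any_nonempty.values()):
        raise ValueError("every threshold yields an empty associated set")

    best_t, best_auc = None, -np.inf
    for t in grid:  # ascending: first strict improvement wins => smallest on ties
        mean_auc = float(np.mean(fold_aucs[t]))
        if mean_auc > best_auc:
            best_t, best_auc = t, mean_auc
    return fit_burden_model(labeled, best_t)
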