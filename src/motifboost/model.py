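"""The k-mer/GBDT repertoire classifier.

The pipeline is: optional count-weighted resampling augmentation of the
training set, k-mer abundance featurization, optional seeded random search
over gradient-boosting hyperparameters scored by group-aware cross-validated
ROC-AUC, and a final classifier trained on all (original + augmented) rows.
A logistic-regression classifier can be substituted for the boosted trees to
ablate the model component; augmentation and hyperparameter search can be
toggled independently.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedGroupKFold

from .augmentation import AugmentationConfig, augment_dataset
from .kmers import FeatureMatrix, featurize_dataset
from .repertoire import RepertoireDataset

CLASSIFIER_GBDT = "gbdt"
CLASSIFIER_LR = "logistic_regression"

#: Fixed numerical choices for the boosted-tree fits (not searched).
#: Features are distribution values in [0, 1]; 31 histogram bins lose no
#: useful resolution at a few hundred training rows and keep fits fast.
#: The small histogram pool avoids allocating per-leaf histogram caches
#: (~6 MB each over 9,261 features) that dominate fit time at wide trees;
#: recomputing histograms is cheap at the few-hundred-row cohorts targeted
#: here, and pool size does not affect the fitted trees.
_GBDT_FIXED = {
    "objective": "binary",
    "verbosity": -1,
    "deterministic": True,
    "force_col_wise": True,
    "max_bin": 31,
    "num_threads": 1,
    "feature_pre_filter": False,
    "histogram_pool_size": 8,
}
_MAX_BOOST_ROUNDS = 300
_EARLY_STOPPING_ROUNDS = 10
_EARLY_STOPPING_MIN_DELTA = 5e-4


@dataclass(frozen=True)
class ModelConfig:
    """Configuration of the full classification pipeline."""

    classifier: str = CLASSIFIER_GBDT
    k: int = 3
    weighting: str = "clone_count"
    enable_hyperparameter_search: bool = True
    search_trials: int = 100
    cv_folds: int = 5
    enable_augmentation: bool = True
    augmentation: AugmentationConfig = field(default_factory=AugmentationConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.classifier not in (CLASSIFIER_GBDT, CLASSIFIER_LR):
            raise ValueError(f"unknown classifier {self.classifier!r}")
        if self.enable_hyperparameter_search and self.search_trials < 1:
            raise ValueError("search_trials must be >= 1 when search is enabled")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


def sample_search_space(rng: np.random.Generator) -> dict:
    """Draw one hyperparameter proposal for the boosted-tree classifier.

    The space is sized for 10^2-10^3 samples by ~10^4 features: learning
    rate and L1/L2 strengths log-uniform, tree capacity on a log2 grid,
    and row/feature subsampling fractions in [0.5, 1].
    """
    return {
        "learning_rate": float(10 ** rng.uniform(np.log10(1e-3), np.log10(0.3))),
        "num_leaves": int(2 ** rng.integers(3, 9)),  # 8..256
        "min_child_samples": int(rng.integers(5, 51)),
        "reg_alpha": float(10 ** rng.uniform(-8, 1)),
        "reg_lambda": float(10 ** rng.uniform(-8, 1)),
        "colsample_bytree": float(rng.uniform(0.5, 1.0)),
        "subsample": float(rng.uniform(0.5, 1.0)),
        "subsample_freq": 1,
    }


def default_gbdt_params() -> dict:
    """LightGBM-default tree parameters, used when search is disabled."""
    return {
        "learning_rate": 0.1,
        "num_leaves": 31,
        "min_child_samples": 20,
        "reg_alpha": 0.0,
        "reg_lambda": 0.0,
        "colsample_bytree": 1.0,
        "subsample": 1.0,
        "subsample_freq": 0,
    }


class FoldConstructionError(ValueError):
    """A cross-validation fold lacked one of the classes."""


def _group_codes(features: FeatureMatrix, groups: dict[str, str]) -> np.ndarray:
    sources = [groups.get(sid, sid) for sid in features.sample_ids]
    _, codes = np.unique(sources, return_inverse=True)
    return codes


def _make_folds(labels: np.ndarray, group_codes: np.ndarray, n_folds: int, seed: int):
    splitter = StratifiedGroupKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = list(splitter.split(np.zeros_like(labels), labels, groups=group_codes))
    for train_idx, val_idx in folds:
        for part in (train_idx, val_idx):
            if len(np.unique(labels[part])) < 2:
                raise FoldConstructionError(
                    f"a class is absent from a {n_folds}-fold split; "
                    "use fewer folds or more samples per class"
                )
    return folds


class _CVData:
    """Pre-binned LightGBM datasets for each CV fold.

    Histogram binning of a few hundred rows by 9,261 features dominates the
    cost of one boosted fit, and the bins depend only on the data, so each
    fold is binned once and shared by every search proposal.
    """

    def __init__(self, features: FeatureMatrix, groups, cv_folds: int, seed: int):
        import lightgbm as lgb

        labels = features.labels
        if labels is None:
            raise ValueError("cross-validation requires labeled features")
        group_codes = _group_codes(features, groups)
        folds = _make_folds(labels, group_codes, cv_folds, seed)
        matrix = features.matrix.astype(np.float32)
        ds_params = dict(_GBDT_FIXED)
        self.folds = []
        for train_idx, val_idx in folds:
            dtrain = lgb.Dataset(
                matrix[train_idx],
                label=labels[train_idx],
                params=ds_params,
                free_raw_data=False,
            )
            dval = dtrain.create_valid(matrix[val_idx], label=labels[val_idx])
            self.folds.append((dtrain, dval))

    def evaluate(self, params: dict, seed: int) -> tuple[float, int]:
        """Mean validation AUC of one proposal, plus mean best round count."""
        import lightgbm as lgb

        aucs, rounds = [], []
        for dtrain, dval in self.folds:
            booster = lgb.train(
                {**_GBDT_FIXED, **params, "metric": "auc", "seed": seed},
                dtrain,
                num_boost_round=_MAX_BOOST_ROUNDS,
                valid_sets=[dval],
                callbacks=[
                    lgb.early_stopping(
                        _EARLY_STOPPING_ROUNDS,
                        verbose=False,
                        min_delta=_EARLY_STOPPING_MIN_DELTA,
                    )
                ],
            )
            aucs.append(booster.best_score["valid_0"]["auc"])
            rounds.append(booster.best_iteration or _MAX_BOOST_ROUNDS)
        return float(np.mean(aucs)), int(np.ceil(np.mean(rounds)))


def cross_validated_auc(
    features: FeatureMatrix,
    groups: dict[str, str],
    params: dict,
    cv_folds: int,
    seed: int,
) -> tuple[float, int]:
    """Mean validation ROC-AUC of one proposal over group-aware stratified
    folds (early stopping on the fold's validation AUC)."""
    return _CVData(features, groups, cv_folds, seed).evaluate(params, seed)


def tune_hyperparameters(
    features: FeatureMatrix,
    groups: dict[str, str],
    config: ModelConfig,
) -> tuple[dict, int]:
    """Seeded random search over the boosted-tree space.

    Each proposal is scored by mean cross-validated ROC-AUC on group-aware
    stratified folds (a source sample and its augmented copies never split
    across folds).  Ties are broken in favor of the first proposal found.
    Returns (best_params, boosting rounds for the final refit).
    """
    rng = np.random.default_rng(config.seed)
    cv_data = _CVData(features, groups, config.cv_folds, config.seed)
    best_params, best_auc, best_rounds = None, -np.inf, 100
    for _trial in range(config.search_trials):
        params = sample_search_space(rng)
        auc, rounds = cv_data.evaluate(params, config.seed)
        if auc > best_auc:
            best_params, best_auc, best_rounds = params, auc, rounds
    return best_params, best_rounds


class _GbdtClassifier:
    """Final boosted-tree model over a pre-binned training set."""

    def __init__(self, params: dict, n_rounds: int, seed: int):
        self.params = {**_GBDT_FIXED, **params, "seed": seed}
        self.n_rounds = n_rounds
        self.booster = None

    def fit(self, matrix: np.ndarray, labels: np.ndarray) -> "_GbdtClassifier":
        import lightgbm as lgb

        dtrain = lgb.Dataset(
            matrix.astype(np.float32), label=labels, params=dict(_GBDT_FIXED)
        )
        self.booster = lgb.train(self.params, dtrain, num_boost_round=self.n_rounds)
        return self

    def predict_proba(self, matrix: np.ndarray) -> np.ndarray:
        p = self.booster.predict(matrix.astype(np.float32))
        return np.column_stack([1 - p, p])

    def __getstate__(self):
        state = self.__dict__.copy()
        if self.booster is not None:
            state["booster"] = self.booster.model_to_string()
        return state

    def __setstate__(self, state):
        import lightgbm as lgb

        booster_str = state.pop("booster", None)
        self.__dict__.update(state)
        self.booster = (
            lgb.Booster(model_str=booster_str) if booster_str is not None else None
        )


@dataclass
class FittedModel:
    """A trained classifier plus the feature specification it expects."""

    config: ModelConfig
    best_hyperparameters: dict | None
    classifier: object
    k: int
    weighting: str
    n_features: int

    def feature_fingerprint(self) -> tuple:
        return (self.k, self.weighting, self.n_features)

    def save(self, path) -> None:
        with open(path, "wb") as fh:
            pickle.dump({"format_version": 1, "model": self}, fh)

    @staticmethod
    def load(path) -> "FittedModel":
        with open(path, "rb") as fh:
            bundle = pickle.load(fh)
        if bundle.get("format_version") != 1:
            raise ValueError("unsupported model bundle version")
        return bundle["model"]


def fit(dataset: RepertoireDataset, config: ModelConfig) -> FittedModel:
    """Train the classifier on a labeled dataset.

    Unlabeled samples are ignored.  Raises if only one class is present.
    """
    train = dataset.labeled()
    if len(train) == 0:
        raise ValueError("no labeled samples to train on")
    if len(np.unique(train.labels)) < 2:
        raise ValueError("training data must contain both classes")

    if config.enable_augmentation and config.augmentation.copies_per_sample > 0:
        train, groups = augment_dataset(train, config.augmentation, config.seed)
    else:
        groups = {s.sample_id: s.sample_id for s in train}

    features = featurize_dataset(train, k=config.k, weighting=config.weighting)

    if config.classifier == CLASSIFIER_LR:
        # Ablation arm: L2 logistic regression at fixed strength, no search.
        clf = LogisticRegression(C=1.0, max_iter=2000, random_state=config.seed)
        clf.fit(features.matrix, features.labels)
        best = None
    else:
        if config.enable_hyperparameter_search:
            best, rounds = tune_hyperparameters(features, groups, config)
            params, n_rounds = best, max(50, min(rounds, _MAX_BOOST_ROUNDS))
        else:
            best, params, n_rounds = None, default_gbdt_params(), 100
        clf = _GbdtClassifier(params, n_rounds, config.seed)
        clf.fit(features.matrix, features.labels)

    return FittedModel(
        config=config,
        best_hyperparameters=best,
        classifier=clf,
        k=config.k,
        weighting=config.weighting,
        n_features=features.n_features,
    )


def predict_scores(model: FittedModel, dataset: RepertoireDataset) -> dict[str, float]:
    """Score samples (higher = more likely positive).  No augmentation is
    ever applied at prediction time."""
    if len(dataset) == 0:
        return {}
    features = featurize_dataset(dataset, k=model.k, weighting=model.weighting)
    if features.n_features != model.n_features:
        raise ValueError(
            f"feature spec mismatch: model expects {model.n_features} features, "
            f"got {features.n_features}"
        )
    probs = model.classifier.predict_proba(features.matrix)[:, 1]
    return dict(zip(features.sample_ids, map(float, probs)))
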