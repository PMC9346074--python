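import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from motifboost.evaluation import (
    BenchmarkMethod,
    axis_projection_auc,
    normalized_ranks,
    optimize_axis_slope,
    prediction_profile_correlation,
    roc_auc,
    run_benchmark,
    stratified_subsample,
    subsample_sequences,
)
from motifboost.repertoire import RepertoireDataset
from tests.conftest import make_sample, random_sample


def concordance_oracle(labels, scores):
    """Brute-force pairwise concordance: P(pos > neg) + 0.5 P(tie)."""
    pos = [s for l, s in zip(labels, scores) if l == 1]
    neg = [s for l, s in zip(labels, scores) if l == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestRocAuc:
    @pytest.mark.parametrize(
        "labels,scores,expected",
        [
            ([1, 1, 0, 0], [0.9, 0.8, 0.2, 0.1], 1.0),
            ([1, 1, 0, 0], [0.5, 0.5, 0.5, 0.5], 0.5),
            ([1, 1, 0, 0], [0.9, 0.2, 0.8, 0.1], 0.75),
        ],
    )
    def test_known_values(self, labels, scores, expected):
        assert roc_auc(labels, scores) == pytest.approx(expected)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 1], [0.3, 0.4])

    @settings(max_examples=200, deadline=None)
    @given(
        n=st.integers(4, 50),
        data=st.data(),
    )
    def test_concordance_oracle(self, n, data):
        labels = data.draw(
            st.lists(st.integers(0, 1), min_size=n, max_size=n).filter(
                lambda ls: 0 < sum(ls) < len(ls)
            )
        )
        # coarse score grid to exercise tie handling
        scores = data.draw(
            st.lists(
                st.integers(0, 5).map(lambda v: v / 5),
                min_size=n,
                max_size=n,
            )
        )
        assert roc_auc(labels, scores) == pytest.approx(
            concordance_oracle(labels, scores)
        )


def _labeled_dataset(n_pos, n_neg, rng, n_seq=10):
    samples = []
    for i in range(n_pos):
        samples.append(random_sample(rng, f"p{i}", n_seq=n_seq, label="positive"))
    for i in range(n_neg):
        samples.append(random_sample(rng, f"n{i}", n_seq=n_seq, label="negative"))
    return RepertoireDataset(samples)


class TestStratifiedSubsample:
    def test_emerson_proportions(self, rng):
        # 289/640 positive; N=25 keeps round(25 * 289/640) = 11 positives
        ds = _labeled_dataset(289, 351, rng, n_seq=2)
        sub = stratified_subsample(ds, 25, rng)
        labels = sub.labels
        assert labels.sum() == 11 and len(labels) == 25

    def test_full_size_returns_everything(self, rng):
        ds = _labeled_dataset(4, 6, rng, n_seq=2)
        sub = stratified_subsample(ds, 10, rng)
        assert sorted(sub.sample_ids) == sorted(ds.sample_ids)

    def test_balanced(self, rng):
        ds = _labeled_dataset(10, 10, rng, n_seq=2)
        sub = stratified_subsample(ds, 10, rng)
        assert sub.labels.sum() == 5

    def test_proportion_deviation_below_one_sample(self, rng):
        ds = _labeled_dataset(13, 27, rng, n_seq=2)
        for n in (5, 11, 20, 33):
            sub = stratified_subsample(ds, n, rng)
            assert abs(sub.labels.sum() - n * 13 / 40) <= 0.5 + 1e-9

    def test_out_of_range_rejected(self, rng):
        ds = _labeled_dataset(3, 3, rng, n_seq=2)
        for n in (1, 7):
            with pytest.raises(ValueError):
                stratified_subsample(ds, n, rng)


class TestSubsampleSequences:
    def test_identity_at_ratio_one(self, toy_dataset, rng):
        out = subsample_sequences(toy_dataset, 1.0, rng)
        for a, b in zip(out, toy_dataset):
            assert a == b

    def test_size_rule(self, rng):
        sample = make_sample("s", {"CASS": 600, "CAR": 400})
        ds = RepertoireDataset([sample])
        out = subsample_sequences(ds, 0.1, rng)
        assert out.samples[0].total_count == 100

    def test_zero_record_sample_named_in_error(self, rng):
        ds = RepertoireDataset([make_sample("tiny", {"CASS": 2})])
        with pytest.raises(ValueError, match="tiny"):
            subsample_sequences(ds, 0.2, rng)

    def test_frequencies_preserved_in_expectation(self, rng):
        sample = make_sample("s", {"CAAA": 700, "CTTT": 200, "CGGG": 100})
        ds = RepertoireDataset([sample])
        totals = {"CAAA": 0, "CTTT": 0, "CGGG": 0}
        reps = 300
        for _ in range(reps):
            out = subsample_sequences(ds, 0.1, rng).samples[0]
            for seq, cnt in zip(out.sequences, out.counts):
                totals[seq] += int(cnt)
        drawn = 100 * reps
        # hypergeometric mean = ratio * count; 5 sigma tolerance ~ 0.009
        assert totals["CAAA"] / drawn == pytest.approx(0.7, abs=0.02)
        assert totals["CGGG"] / drawn == pytest.approx(0.1, abs=0.02)


class _CountBurdenMethod(BenchmarkMethod):
    """Deterministic toy method: score = fraction of sequences seen in
    positive training samples."""

    name = "toy"

    def fit_score(self, train, test, seed):
        pos_seqs = set()
        for s in train:
            if s.label_binary == 1:
                pos_seqs |= set(s.sequences)
        return {
            s.sample_id: sum(q in pos_seqs for q in s.sequences) / s.n_unique
            for s in test
        }


class TestRunBenchmark:
    def _data(self, rng):
        train = _labeled_dataset(8, 8, rng, n_seq=6)
        test = RepertoireDataset(
            [
                s.with_id(f"t_{s.sample_id}")
                for s in _labeled_dataset(4, 4, rng, n_seq=6)
            ]
        )
        return train, test

    def test_trial_count(self, rng):
        train, test = self._data(rng)
        report = run_benchmark(
            [_CountBurdenMethod()], train, test, sizes=[10], trials_per_size=3, seed=0
        )
        assert len(report.results) == 3
        assert report.summary()["n_trials"].tolist() == [3]

    def test_report_reproducible_from_master_seed(self, rng):
        train, test = self._data(rng)
        kwargs = dict(sizes=[6, 10], trials_per_size=2, seed=99)
        r1 = run_benchmark([_CountBurdenMethod()], train, test, **kwargs)
        r2 = run_benchmark([_CountBurdenMethod()], train, test, **kwargs)
        assert r1.to_frame().equals(r2.to_frame())

    def test_deterministic_method_identical_across_trial_repeats(self, rng):
        train, test = self._data(rng)
        method = _CountBurdenMethod()
        r1 = run_benchmark([method], train, test, sizes=[10], trials_per_size=1, seed=5)
        trial = r1.results[0]
        rng2 = np.random.default_rng(trial.seed)
        sub = stratified_subsample(train, 10, rng2)
        again = method.fit_score(sub, test.labeled(), trial.seed)
        assert again == trial.scores

    def test_train_test_overlap_rejected(self, rng):
        train, _ = self._data(rng)
        with pytest.raises(ValueError):
            run_benchmark([_CountBurdenMethod()], train, train, sizes=[4],
                          trials_per_size=1, seed=0)


class TestAxisProjection:
    def test_separating_axis(self):
        coords = [(0, 0), (0, 1), (1, 0), (1, 1)]
        labels = [0, 0, 1, 1]
        assert axis_projection_auc(coords, labels, (1, 0)) == 1.0

    def test_orthogonal_axis_is_chance(self):
        coords = [(0, 0), (0, 1), (1, 0), (1, 1)]
        labels = [0, 0, 1, 1]
        assert axis_projection_auc(coords, labels, (0, 1)) == 0.5

    def test_zero_axis_rejected(self):
        with pytest.raises(ValueError):
            axis_projection_auc([(0, 0), (1, 1)], [0, 1], (0, 0))

    def test_slope_search_recovers_separation(self, rng):
        # classes lie on parallel lines y = -x + c (c = 1 vs 0) with a wide
        # spread along the lines: only axes near y = x separate them
        t = rng.uniform(0, 3, size=20)
        pos = np.column_stack([t, -t + 1.0])
        neg = np.column_stack([t, -t])
        coords = np.vstack([pos, neg])
        labels = [1] * 20 + [0] * 20
        slope, auc = optimize_axis_slope(coords, labels)
        assert auc == 1.0
        assert 0.5 < slope < 2.0


class TestPredictionProfiles:
    def test_identical_profiles(self):
        a = {"s1": 0.1, "s2": 0.5, "s3": 0.9, "s4": 0.2}
        assert prediction_profile_correlation(a, dict(a)) == pytest.approx(1.0)

    def test_reversed_profiles(self):
        a = {"s1": 1.0, "s2": 2.0, "s3": 3.0, "s4": 4.0}
        b = {k: -v for k, v in a.items()}
        assert prediction_profile_correlation(a, b) == pytest.approx(-1.0)

    def test_single_swap_spearman(self):
        # ranks (1,2,3,4) vs (1,2,4,3): rho = 1 - 6*2/(4*15) = 0.8
        a = {"s1": 1, "s2": 2, "s3": 3, "s4": 4}
        b = {"s1": 1, "s2": 2, "s3": 4, "s4": 3}
        assert prediction_profile_correlation(a, b) == pytest.approx(0.8)

    def test_too_few_common_samples_rejected(self):
        with pytest.raises(ValueError):
            prediction_profile_correlation({"a": 1, "b": 2}, {"a": 2, "b": 1})

    def test_normalized_ranks_span_unit_interval(self):
        ranks = normalized_ranks({"a": 10.0, "b": -3.0, "c": 5.0})
        assert ranks["b"] == 0.0 and ranks["a"] == 1.0 and ranks["c"] == 0.5
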