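import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from motifboost.burden import (
    DegenerateBurdenError,
    betabinom_loglik,
    build_association_table,
    compute_burden,
    fisher_exact_one_sided,
    fit_betabinomial,
    fit_burden_model,
    method_of_moments,
    predict_burden_scores,
    score_burden,
    tune_threshold,
)
from motifboost.repertoire import RepertoireDataset
from tests.conftest import make_sample


def hypergeom_tail_oracle(a, b, c, d):
    """Exact upper-tail sum with integer binomials (independent oracle)."""
    n_pos, n_present, total = a + b, a + c, a + b + c + d
    denom = math.comb(total, n_pos)
    tail = 0
    for x in range(a, min(n_pos, n_present) + 1):
        tail += math.comb(n_present, x) * math.comb(total - n_present, n_pos - x)
    return tail / denom


class TestFisherExact:
    def test_all_positive_all_absent_negative(self):
        # 5/5 positives have it, 0/5 negatives: p = 1 / C(10,5)
        assert fisher_exact_one_sided(5, 0, 0, 5) == pytest.approx(
            1 / math.comb(10, 5), abs=1e-12
        )

    def test_observed_minimum_gives_one(self):
        assert fisher_exact_one_sided(0, 5, 0, 5) == pytest.approx(1.0)

    def test_tail_sum_example(self):
        assert fisher_exact_one_sided(3, 2, 2, 3) == pytest.approx(
            hypergeom_tail_oracle(3, 2, 2, 3), abs=1e-12
        )

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_one_sided(-1, 2, 3, 4)

    @settings(max_examples=200, deadline=None)
    @given(
        n1=st.integers(0, 30),
        n2=st.integers(0, 30),
        data=st.data(),
    )
    def test_oracle_agreement_random_tables(self, n1, n2, data):
        a = data.draw(st.integers(0, n1))
        c = data.draw(st.integers(0, n2))
        p = fisher_exact_one_sided(a, n1 - a, c, n2 - c)
        assert p == pytest.approx(hypergeom_tail_oracle(a, n1 - a, c, n2 - c), abs=1e-12)

    def test_monotone_in_positive_presence(self):
        # moving one presence from negatives to positives (margins fixed)
        p_values = [fisher_exact_one_sided(a, 10 - a, 6 - a, 4 + a) for a in range(7)]
        assert all(x >= y for x, y in zip(p_values, p_values[1:]))


@pytest.fixture
def assoc_dataset():
    samples = [
        make_sample("p1", {"CAQQ": 1, "CASS": 2}, label="positive"),
        make_sample("p2", {"CAQQ": 3, "CASS": 1}, label="positive"),
        make_sample("p3", {"CAQQ": 2, "CASS": 1, "CAYY": 1}, label="positive"),
        make_sample("n1", {"CASS": 1, "CADD": 2}, label="negative"),
        make_sample("n2", {"CASS": 4}, label="negative"),
        make_sample("n3", {"CASS": 2, "CAEE": 1}, label="negative"),
    ]
    return RepertoireDataset(samples)


class TestAssociationTable:
    def test_perfectly_enriched_sequence(self, assoc_dataset):
        table = build_association_table(assoc_dataset)
        # CAQQ in 3/3 positives, 0/3 negatives: p = 1/C(6,3) = 0.05
        assert table.table.loc["CAQQ", "p_value"] == pytest.approx(0.05, abs=1e-12)

    def test_ubiquitous_sequence_p_one(self, assoc_dataset):
        table = build_association_table(assoc_dataset)
        assert table.table.loc["CASS", "p_value"] == pytest.approx(1.0)

    def test_covers_exactly_union_of_sequences(self, assoc_dataset):
        table = build_association_table(assoc_dataset)
        union = set()
        for s in assoc_dataset:
            union |= set(s.sequences)
        assert set(table.sequences) == union

    def test_presence_is_count_insensitive(self, assoc_dataset):
        table = build_association_table(assoc_dataset)
        assert table.table.loc["CAQQ", "n_pos_present"] == 3
        assert table.table.loc["CAQQ", "n_neg_present"] == 0

    def test_single_class_rejected(self):
        ds = RepertoireDataset(
            [make_sample("p1", {"CASS": 1}, label="positive")]
        )
        with pytest.raises(ValueError):
            build_association_table(ds)


class TestComputeBurden:
    def test_basic(self, assoc_dataset):
        sample = assoc_dataset["p3"]
        assert compute_burden(sample, {"CAQQ", "CAYY"}) == (2, 3)

    def test_empty_set(self, assoc_dataset):
        assert compute_burden(assoc_dataset["p1"], set()) == (0, 2)

    def test_full_containment(self, assoc_dataset):
        sample = assoc_dataset["n1"]
        assert compute_burden(sample, set(sample.sequences)) == (2, 2)


class TestBetaBinomialFit:
    def test_parameter_recovery(self, rng):
        from scipy import stats

        n = 1000
        p = stats.beta.rvs(2.0, 50.0, size=200, random_state=rng)
        xs = rng.binomial(n, p)
        alpha, beta = fit_betabinomial([(int(x), n) for x in xs])
        assert abs(alpha - 2.0) / 2.0 < 0.3
        assert abs(beta - 50.0) / 50.0 < 0.3

    def test_ascent_from_mom_initializer(self, rng):
        from scipy import stats

        n = 500
        p = stats.beta.rvs(3.0, 20.0, size=100, random_state=rng)
        xs = np.array([rng.binomial(n, pi) for pi in p], dtype=float)
        ns = np.full(100, float(n))
        burdens = [(int(x), n) for x in xs]
        alpha, beta = fit_betabinomial(burdens)
        a0, b0 = method_of_moments(xs, ns)
        assert betabinom_loglik(alpha, beta, xs, ns) >= betabinom_loglik(
            a0, b0, xs, ns
        )

    def test_grid_oracle_agreement(self, rng):
        from scipy import stats

        n = 1000
        p = stats.beta.rvs(2.0, 50.0, size=200, random_state=rng)
        xs = np.array([rng.binomial(n, pi) for pi in p], dtype=float)
        ns = np.full(200, float(n))
        alpha, beta = fit_betabinomial([(int(x), int(m)) for x, m in zip(xs, ns)])
        ll_fit = betabinom_loglik(alpha, beta, xs, ns)
        grid_a = np.geomspace(alpha / 3, alpha * 3, 101)
        grid_b = np.geomspace(beta / 3, beta * 3, 101)
        ll_grid = max(
            betabinom_loglik(a, b, xs, ns) for a in grid_a for b in grid_b
        )
        assert ll_fit >= ll_grid - 1e-4

    def test_degenerate_input_prescribes_fallback(self):
        with pytest.raises(DegenerateBurdenError):
            fit_betabinomial([(0, 10), (0, 12), (0, 9)])


class TestBurdenScoring:
    def test_identical_class_models_score_zero(self, assoc_dataset):
        model = fit_burden_model(assoc_dataset, p_threshold=0.05)
        symmetric = type(model)(
            associated_set=model.associated_set,
            p_threshold=model.p_threshold,
            positive_model=model.positive_model,
            negative_model=model.positive_model,
        )
        for sample in assoc_dataset:
            assert score_burden(symmetric, sample) == 0.0

    def test_direction(self, assoc_dataset):
        model = fit_burden_model(assoc_dataset, p_threshold=0.05)
        assert "CAQQ" in model.associated_set
        pos_scores = [score_burden(model, assoc_dataset[f"p{i}"]) for i in (1, 2, 3)]
        neg_scores = [score_burden(model, assoc_dataset[f"n{i}"]) for i in (1, 2, 3)]
        assert min(pos_scores) > max(neg_scores)

    def test_bitwise_deterministic(self, assoc_dataset):
        m1 = fit_burden_model(assoc_dataset, p_threshold=0.05)
        m2 = fit_burden_model(assoc_dataset, p_threshold=0.05)
        s1 = predict_burden_scores(m1, assoc_dataset)
        s2 = predict_burden_scores(m2, assoc_dataset)
        assert s1 == s2


class TestTuneThreshold:
    def test_single_grid_point_selected(self, assoc_dataset):
        # 3-fold CV trains on 4 samples (2 pos / 2 neg), where the smallest
        # attainable p-value is 1/C(4,2) = 1/6, so 0.2 is reachable
        model = tune_threshold(assoc_dataset, grid=[0.2], cv_folds=3, seed=0)
        assert model.p_threshold == 0.2

    def test_all_empty_sets_error(self, assoc_dataset):
        with pytest.raises(ValueError):
            tune_threshold(assoc_dataset, grid=[1e-12], cv_folds=3, seed=0)
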