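import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from emrkg import models
from emrkg.models import (
    DegenerateLabelError,
    fit_logistic,
    fit_naive_bayes,
    fit_noisy_or,
    noisy_or_log_likelihood,
    noisy_or_symptom_prob,
)


class TestLogistic:
    def _toy(self, matrix_factory):
        # symptom s0 perfectly co-occurs with the disease; s1 is noise
        rng = np.random.default_rng(0)
        y = np.repeat([1, 0], [10, 10])
        X = np.column_stack([y, rng.integers(0, 2, 20)])
        return matrix_factory(y[:, None], X)

    def test_perfect_cooccurrence_gets_positive_weight(self, matrix_factory):
        m = fit_logistic(self._toy(matrix_factory), "d0", l1_grid=[0.01], seed=1)
        assert m.weights[m.symptom_ids.index("s0")] > 0

    def test_single_grid_value_skips_selection(self, matrix_factory):
        m = fit_logistic(self._toy(matrix_factory), "d0", l1_grid=[0.5])
        assert m.l1_strength == 0.5 and m.cv_losses == {}

    def test_extreme_l1_shrinks_all_weights_to_zero(self, matrix_factory):
        m = fit_logistic(self._toy(matrix_factory), "d0", l1_grid=[1e6])
        assert np.allclose(m.weights, 0.0)

    def test_degenerate_label_raises(self, matrix_factory):
        mat = matrix_factory(np.ones((10, 1)), np.zeros((10, 2)))
        with pytest.raises(DegenerateLabelError, match="degenerate label"):
            fit_logistic(mat, "d0")

    def test_cv_selection_invariant_to_patient_order(self, matrix_factory):
        rng = np.random.default_rng(3)
        y = rng.integers(0, 2, 60)
        X = np.column_stack([y ^ (rng.random(60) < 0.2), rng.integers(0, 2, (60, 2))])
        mat = matrix_factory(y[:, None], X)
        perm = rng.permutation(60)
        shuffled = matrix_factory(
            y[perm][:, None], X[perm], brackets=["adult"] * 60
        )
        shuffled.patients = [mat.patients[i] for i in perm]
        a = fit_logistic(mat, "d0", seed=11)
        b = fit_logistic(shuffled, "d0", seed=11)
        assert a.l1_strength == b.l1_strength
        assert np.allclose(a.weights, b.weights, atol=1e-6)


class TestNaiveBayes:
    def test_hand_counted_conditionals(self, matrix_factory):
        # disease present in 10 records (symptom on in 4), absent in 90 (on in 9)
        y = np.repeat([1, 0], [10, 90])
        x = np.zeros(100, dtype=int)
        x[:4] = 1
        x[10:19] = 1
        mat = matrix_factory(y[:, None], x[:, None])
        m = fit_naive_bayes(mat, "d0", pseudocount_grid=[1.0])
        assert m.p_present[0] == pytest.approx(5 / 12)
        assert m.p_absent[0] == pytest.approx(10 / 92)

    def test_heavy_smoothing_pulls_conditionals_to_half(self, matrix_factory):
        y = np.repeat([1, 0], [10, 90])
        x = np.zeros(100, dtype=int)
        x[:4] = 1
        mat = matrix_factory(y[:, None], x[:, None])
        m = fit_naive_bayes(mat, "d0", pseudocount_grid=[1e6])
        assert m.p_present[0] == pytest.approx(0.5, abs=1e-3)
        assert m.p_absent[0] == pytest.approx(0.5, abs=1e-3)

    def test_unseen_symptom_stays_strictly_positive(self, matrix_factory):
        y = np.repeat([1, 0], [10, 10])
        mat = matrix_factory(y[:, None], np.zeros((20, 1)))
        m = fit_naive_bayes(mat, "d0", pseudocount_grid=[1.0])
        assert 0.0 < m.p_present[0] < 1.0 and 0.0 < m.p_absent[0] < 1.0

    def test_degenerate_label_raises(self, matrix_factory):
        mat = matrix_factory(np.zeros((10, 1)), np.zeros((10, 1)))
        with pytest.raises(DegenerateLabelError):
            fit_naive_bayes(mat, "d0")

    def test_cv_selects_from_grid(self, matrix_factory):
        rng = np.random.default_rng(5)
        y = rng.integers(0, 2, 90)
        X = rng.integers(0, 2, (90, 3))
        m = fit_naive_bayes(matrix_factory(y[:, None], X), "d0", seed=2)
        assert m.pseudocount in {0.1, 0.5, 1.0, 2.0, 5.0}
        assert len(m.cv_loglik) == 5


class TestNoisyOrConditional:
    @pytest.mark.parametrize(
        "y,f,leak,expected",
        [
            ([0, 0], [0.2, 0.5], 0.1, 0.1),
            ([1, 0], [0.2, 0.5], 0.1, 0.82),
            ([1, 1], [0.5, 0.5], 0.0, 0.75),
        ],
    )
    def test_closed_form(self, y, f, leak, expected):
        assert noisy_or_symptom_prob(np.array(y), np.array(f), leak) == pytest.approx(
            expected
        )

    def test_out_of_range_probability_rejected(self):
        with pytest.raises(ValueError):
            noisy_or_symptom_prob(np.array([1]), np.array([1.2]), 0.1)

    @settings(max_examples=50, deadline=None)
    @given(
        f=st.lists(st.floats(0, 1), min_size=1, max_size=5),
        leak=st.floats(0, 1),
        data=st.data(),
    )
    def test_activating_parent_never_decreases_probability(self, f, leak, data):
        f = np.asarray(f)
        y = np.asarray(data.draw(st.lists(st.sampled_from([0, 1]), min_size=len(f), max_size=len(f))))
        off = data.draw(st.integers(0, len(f) - 1))
        y_on = y.copy()
        y_on[off] = 1
        assert noisy_or_symptom_prob(y_on, f, leak) >= noisy_or_symptom_prob(
            y, f, leak
        ) - 1e-12


class TestNoisyOrLikelihood:
    def test_single_cell(self, matrix_factory):
        mat = matrix_factory([[0]], [[1]])
        model = models.NoisyOrModel(
            disease_ids=["d0"],
            symptom_ids=["s0"],
            failure=np.array([[0.5]]),
            leak=np.array([0.1]),
        )
        assert noisy_or_log_likelihood(model, mat) == pytest.approx(np.log(0.1))

    def test_empty_matrix(self, matrix_factory):
        mat = matrix_factory(np.zeros((0, 1)), np.zeros((0, 1)))
        model = models.NoisyOrModel(
            disease_ids=["d0"],
            symptom_ids=["s0"],
            failure=np.array([[0.5]]),
            leak=np.array([0.1]),
        )
        assert noisy_or_log_likelihood(model, mat) == 0.0

    def test_matches_per_cell_brute_force(self, matrix_factory):
        rng = np.random.default_rng(7)
        Y = rng.integers(0, 2, (5, 3))
        X = rng.integers(0, 2, (5, 4))
        mat = matrix_factory(Y, X)
        F = rng.uniform(0.1, 0.9, (4, 3))
        L = rng.uniform(0.05, 0.3, 4)
        model = models.NoisyOrModel(
            disease_ids=mat.disease_ids, symptom_ids=mat.symptom_ids, failure=F, leak=L
        )
        expected = 0.0
        for p in range(5):
            for i in range(4):
                prob = noisy_or_symptom_prob(Y[p], F[i], L[i])
                expected += np.log(prob) if X[p, i] else np.log(1 - prob)
        assert noisy_or_log_likelihood(model, mat) == pytest.approx(expected)


def _grid_best_ll(mat, grid_size=200):
    """Independent 2-parameter grid-search oracle for a 1x1 instance."""
    y = mat.disease_block()[:, 0].astype(float)
    x = mat.symptom_block()[:, 0].astype(float)
    vals = np.linspace(1e-4, 1 - 1e-4, grid_size)
    best = -np.inf
    for f in vals:
        p1 = np.clip(1 - (1 - vals) * f, 1e-9, 1 - 1e-9)  # p(x=1|y=1) per leak
        p0 = np.clip(vals, 1e-9, 1 - 1e-9)  # p(x=1|y=0) = leak
        n11 = ((y == 1) & (x == 1)).sum()
        n10 = ((y == 1) & (x == 0)).sum()
        n01 = ((y == 0) & (x == 1)).sum()
        n00 = ((y == 0) & (x == 0)).sum()
        ll = (
            n11 * np.log(p1)
            + n10 * np.log(1 - p1)
            + n01 * np.log(p0)
            + n00 * np.log(1 - p0)
        )
        best = max(best, ll.max())
    return best


class TestFitNoisyOr:
    def test_deterministic_pair_drives_failure_and_leak_to_zero(self, matrix_factory):
        rng = np.random.default_rng(11)
        y = (rng.random(10_000) < 0.3).astype(np.int8)
        mat = matrix_factory(y[:, None], y[:, None])
        m = fit_noisy_or(mat)
        assert m.failure[0, 0] <= 0.01
        assert m.leak[0] <= 0.01

    def test_parameter_recovery(self, matrix_factory):
        rng = np.random.default_rng(12)
        n = 50_000
        y = (rng.random(n) < 0.3).astype(np.int8)
        p = 1 - (1 - 0.05) * np.where(y == 1, 0.3, 1.0)
        x = (rng.random(n) < p).astype(np.int8)
        m = fit_noisy_or(matrix_factory(y[:, None], x[:, None]))
        assert abs(m.failure[0, 0] - 0.3) <= 0.02
        assert abs(m.leak[0] - 0.05) <= 0.01

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_fit_attains_grid_search_optimum(self, matrix_factory, seed):
        rng = np.random.default_rng(seed)
        n = 400
        y = (rng.random(n) < rng.uniform(0.2, 0.5)).astype(np.int8)
        f_true, l_true = rng.uniform(0.2, 0.8), rng.uniform(0.02, 0.2)
        p = 1 - (1 - l_true) * np.where(y == 1, f_true, 1.0)
        x = (rng.random(n) < p).astype(np.int8)
        mat = matrix_factory(y[:, None], x[:, None])
        m = fit_noisy_or(mat)
        assert m.log_likelihood >= _grid_best_ll(mat) - 1e-3

    def test_trace_monotone_and_final_at_least_initial(self, matrix_factory):
        rng = np.random.default_rng(13)
        Y = rng.integers(0, 2, (500, 3))
        X = rng.integers(0, 2, (500, 5))
        m = fit_noisy_or(matrix_factory(Y, X))
        assert m.log_likelihood >= m.initial_log_likelihood
        for trace in m.ll_traces:
            assert all(b >= a for a, b in zip(trace, trace[1:]))

    def test_requires_disease_and_symptom_columns(self, matrix_factory):
        mat = matrix_factory(np.zeros((5, 1)), np.zeros((5, 0)))
        with pytest.raises(ValueError, match="at least one"):
            fit_noisy_or(mat)

    def test_serialization_round_trip(self, matrix_factory):
        rng = np.random.default_rng(14)
        mat = matrix_factory(rng.integers(0, 2, (200, 2)), rng.integers(0, 2, (200, 3)))
        m = fit_noisy_or(mat)
        again = models.model_from_dict(models.model_to_dict(m))
        assert np.allclose(again.failure, m.failure)
        assert np.allclose(again.leak, m.leak)
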