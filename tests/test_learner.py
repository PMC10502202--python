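import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hbsl.learner import (
    DirichletMarkovModel,
    bayesian_surprise,
    conditional_entropy,
    empirical_context_weights,
    learn_sequence,
)


def beta_var(alpha_i, alpha_0):
    """Independent closed-form oracle for the marginal Beta variance."""
    return alpha_i * (alpha_0 - alpha_i) / (alpha_0**2 * (alpha_0 + 1))


class TestInit:
    def test_uniform_prior_predictive(self):
        model = DirichletMarkovModel(K=3)
        assert model.predictive((0,)) == pytest.approx([1 / 3] * 3)

    def test_sensitivity_scales_variance_not_mean(self):
        normal = DirichletMarkovModel(K=3, sensitivity_factor=1)
        hyper = DirichletMarkovModel(K=3, sensitivity_factor=4)
        assert hyper.predictive((0,)) == pytest.approx(normal.predictive((0,)))
        v_normal = normal.transition_estimate((0,), 1).variance
        v_hyper = hyper.transition_estimate((0,), 1).variance
        # oracle: evaluate the Beta-variance formula at alpha_0 = 3 and 12
        assert v_normal == pytest.approx(beta_var(1, 3))
        assert v_hyper == pytest.approx(beta_var(4, 12))
        assert v_hyper < v_normal

    @pytest.mark.parametrize(
        "kwargs", [{"K": 1}, {"K": 3, "sensitivity_factor": 0},
                   {"K": 3, "sensitivity_factor": -1},
                   {"K": 3, "base_concentration": 0}, {"K": 3, "order": 0}]
    )
    def test_invalid_parameters_raise(self, kwargs):
        with pytest.raises(ValueError):
            DirichletMarkovModel(**kwargs)


class TestObserve:
    def test_conjugate_count(self):
        model = DirichletMarkovModel(K=3)
        model.observe((0,), 1)
        assert model.row_alpha((0,)).tolist() == [1, 2, 1]

    def test_nine_of_ten_posterior(self):
        model = DirichletMarkovModel(K=2)
        for _ in range(9):
            model.observe((0,), 1)
        model.observe((0,), 0)
        assert model.row_alpha((0,)).tolist() == [2, 10]
        assert model.predictive((0,))[1] == pytest.approx(10 / 12)

    def test_other_contexts_untouched(self):
        model = DirichletMarkovModel(K=3)
        model.observe((0,), 1)
        assert model.counts((1,)).tolist() == [0, 0, 0]
        assert model.counts((2,)).tolist() == [0, 0, 0]

    def test_out_of_alphabet_raises(self):
        model = DirichletMarkovModel(K=3)
        with pytest.raises(IndexError):
            model.observe((0,), 3)
        with pytest.raises(IndexError):
            model.observe((5,), 0)

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.tuples(st.integers(0, 3), st.integers(0, 3)), max_size=60))
    def test_conjugacy_matches_counting_oracle(self, stream):
        """After any stream, each row equals prior + independent per-pair counts."""
        model = DirichletMarkovModel(K=4)
        tally = {}
        for ctx, sym in stream:
            model.observe((ctx,), sym)
            tally[(ctx, sym)] = tally.get((ctx, sym), 0) + 1
        for ctx in range(4):
            expected = np.ones(4)
            for sym in range(4):
                expected[sym] += tally.get((ctx, sym), 0)
            np.testing.assert_allclose(model.row_alpha((ctx,)), expected)
            assert model.predictive((ctx,)).sum() == pytest.approx(1, abs=1e-12)


class TestTransitionEstimate:
    def test_count_ratio_nine_of_ten_is_090(self):
        model = DirichletMarkovModel(K=2)
        for _ in range(9):
            model.observe((0,), 1)
        model.observe((0,), 0)
        est = model.transition_estimate((0,), 1, estimator="count_ratio")
        assert est.mean == pytest.approx(0.90)

    def test_more_evidence_means_more_reliability(self):
        """9/10 vs 90/100 share a 0.9 count ratio but not a reliability."""
        small = DirichletMarkovModel(K=2)
        large = DirichletMarkovModel(K=2)
        for _ in range(9):
            small.observe((0,), 1)
        small.observe((0,), 0)
        for _ in range(90):
            large.observe((0,), 1)
        for _ in range(10):
            large.observe((0,), 0)
        est_small = small.transition_estimate((0,), 1, estimator="count_ratio")
        est_large = large.transition_estimate((0,), 1, estimator="count_ratio")
        assert est_small.mean == est_large.mean == pytest.approx(0.9)
        # Beta-variance oracle computed independently
        assert est_small.variance == pytest.approx(beta_var(10, 12), rel=1e-12)
        assert est_large.variance == pytest.approx(beta_var(91, 102), rel=1e-12)
        assert est_large.reliability > est_small.reliability

    def test_unobserved_context_uniform(self):
        model = DirichletMarkovModel(K=4)
        est = model.transition_estimate((2,), 1, estimator="count_ratio")
        assert est.mean == pytest.approx(0.25)

    def test_reliability_increases_with_observations(self):
        model = DirichletMarkovModel(K=3)
        rels = []
        for _ in range(20):
            model.observe((0,), 1)
            rels.append(model.transition_estimate((0,), 1).reliability)
        assert all(b > a for a, b in zip(rels, rels[1:]))

    def test_initial_reliability_ordering_across_regimes(self):
        rel = {
            f: DirichletMarkovModel(K=8, sensitivity_factor=f)
            .transition_estimate((0,), 1)
            .reliability
            for f in (0.25, 1.0, 4.0)
        }
        assert rel[4.0] > rel[1.0] > rel[0.25]

    def test_identical_count_increments_across_regimes(self):
        stream = [(0, 1), (1, 2), (0, 1), (2, 0)]
        counts = {}
        for f in (0.25, 1.0, 4.0):
            model = DirichletMarkovModel(K=3, sensitivity_factor=f)
            for ctx, sym in stream:
                model.observe((ctx,), sym)
            counts[f] = {c: model.counts(c).tolist() for c in model.contexts}
        assert counts[0.25] == counts[1.0] == counts[4.0]


class TestBayesianSurprise:
    def test_identical_distributions_zero(self):
        assert bayesian_surprise([0.5, 0.5], [0.5, 0.5]) == 0.0

    def test_hand_evaluated_value(self):
        # independent summation oracle: 0.9 ln(0.9/0.5) + 0.1 ln(0.1/0.5)
        expected = 0.9 * math.log(0.9 / 0.5) + 0.1 * math.log(0.1 / 0.5)
        assert bayesian_surprise([0.9, 0.1], [0.5, 0.5]) == pytest.approx(
            expected, abs=1e-12
        )
        assert expected == pytest.approx(0.3681, abs=5e-5)

    def test_asymmetric(self):
        fwd = bayesian_surprise([0.9, 0.1], [0.5, 0.5])
        bwd = bayesian_surprise([0.5, 0.5], [0.9, 0.1])
        assert fwd != pytest.approx(bwd)

    @pytest.mark.parametrize(
        "p,q",
        [([0.5, 0.5], [0.5, 0.5, 0.0]), ([0.6, 0.6], [0.5, 0.5]),
         ([1.0, 0.0], [0.5, 0.5])],
    )
    def test_invalid_inputs_raise(self, p, q):
        with pytest.raises(ValueError):
            bayesian_surprise(p, q)

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(0.01, 10), min_size=2, max_size=6),
           st.lists(st.floats(0.01, 10), min_size=2, max_size=6))
    def test_nonnegative(self, a, b):
        n = min(len(a), len(b))
        p = np.array(a[:n]) / np.sum(a[:n])
        q = np.array(b[:n]) / np.sum(b[:n])
        assert bayesian_surprise(p / p.sum(), q / q.sum()) >= 0


class TestConditionalEntropy:
    def test_uniform_rows_log2k(self):
        model = DirichletMarkovModel(K=4)
        h = conditional_entropy(model, {(0,): 0.5, (1,): 0.5})
        assert h == pytest.approx(2.0)

    def test_near_deterministic_rows_near_zero(self):
        model = DirichletMarkovModel(K=4, base_concentration=1e-4)
        for _ in range(200):
            model.observe((0,), 1)
        h = conditional_entropy(model, {(0,): 1.0})
        assert h < 0.02

    def test_mixed_rows_weighted_formula(self):
        # oracle: 0.5 * H2(0.9) + 0.5 * 1 bit, evaluated directly
        model = DirichletMarkovModel(K=2, base_concentration=1e-9)
        for _ in range(9):
            model.observe((0,), 0)
        model.observe((0,), 1)
        model.observe((1,), 0)
        model.observe((1,), 1)
        h2 = -(0.9 * math.log2(0.9) + 0.1 * math.log2(0.1))
        h = conditional_entropy(model, {(0,): 0.5, (1,): 0.5})
        assert h == pytest.approx(0.5 * h2 + 0.5, abs=1e-6)

    def test_bad_weights_raise(self):
        model = DirichletMarkovModel(K=3)
        with pytest.raises(ValueError):
            conditional_entropy(model, {(0,): 0.7})

    def test_empirical_weights_sum_to_one(self, fixture_tokens):
        w = empirical_context_weights(fixture_tokens.tokens)
        assert sum(w.values()) == pytest.approx(1.0)


class TestLearnSequence:
    def test_too_short_sequence_is_noop(self):
        model = DirichletMarkovModel(K=3)
        model, trace = learn_sequence(model, [1])
        assert trace.total_surprise == 0
        assert model.contexts == []

    def test_total_equals_sum_of_events(self, fixture_tokens):
        model = DirichletMarkovModel(K=fixture_tokens.K)
        _, trace = learn_sequence(model, fixture_tokens.tokens)
        assert trace.total_surprise == pytest.approx(sum(trace.per_event_surprise))
        assert len(trace.per_event_surprise) == len(fixture_tokens) - 1

    def test_surprise_non_increasing_over_trials(self, fixture_tokens):
        model = DirichletMarkovModel(K=fixture_tokens.K)
        totals = []
        for trial in range(1, 6):
            model, trace = learn_sequence(model, fixture_tokens.tokens, trial)
            totals.append(trace.total_surprise)
        assert all(b <= a for a, b in zip(totals, totals[1:]))

    def test_surprise_ordering_across_regimes(self, trained_models):
        for trial in range(5):
            hypo = trained_models["hypo"][1][trial].total_surprise
            normal = trained_models["normal"][1][trial].total_surprise
            hyper = trained_models["hyper"][1][trial].total_surprise
            assert hypo > normal > hyper


class TestSerialization:
    def test_json_roundtrip(self, fixture_tokens):
        model = DirichletMarkovModel(K=fixture_tokens.K, sensitivity_factor=4)
        learn_sequence(model, fixture_tokens.tokens)
        back = DirichletMarkovModel.from_json(model.to_json())
        assert back.K == model.K
        assert back.sensitivity_factor == model.sensitivity_factor
        for ctx in model.contexts:
            np.testing.assert_allclose(back.row_alpha(ctx), model.row_alpha(ctx))
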