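"""Belief- and trust-update arithmetic against closed-form oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from testinet.model_core import (
    ReportContent,
    TrustKind,
    TrustState,
    belief_update_batch,
    belief_update_single,
    expected_trust,
    fixed_trust_belief_closed_form,
    predictive_report_prob,
    simpson_weights,
    trust_update,
)

from conftest import BetaMixtureOracle

H = ReportContent.ASSERT_H
NOT_H = ReportContent.ASSERT_NOT_H

probs = st.floats(min_value=0.0, max_value=1.0, allow_nan=False)
open_probs = st.floats(min_value=0.01, max_value=0.99, allow_nan=False)


class TestBeliefUpdateSingle:
    @pytest.mark.parametrize(
        "belief, rho, content, expected",
        [
            (0.5, 0.66, H, 0.66),                 # uniform prior returns the reliability
            (0.7, 0.5, H, 0.7),                   # uninformative source: no change
            (0.7, 0.5, NOT_H, 0.7),
            (0.8, 0.66, NOT_H, 0.272 / 0.404),    # direct Bayes arithmetic
            (0.0, 0.66, H, 0.0),                  # dogmatic beliefs are absorbing
            (1.0, 0.66, NOT_H, 1.0),
        ],
    )
    def test_matches_bayes_rule(self, belief, rho, content, expected):
        assert belief_update_single(belief, rho, content) == pytest.approx(
            expected, abs=1e-12
        )

    @pytest.mark.parametrize("rho", [0.0, 1.0, -0.1, 1.5])
    def test_degenerate_reliability_rejected(self, rho):
        with pytest.raises(ValueError):
            belief_update_single(0.5, rho, H)

    @pytest.mark.parametrize("belief", [-0.01, 1.01, float("nan")])
    def test_invalid_belief_rejected(self, belief):
        with pytest.raises(ValueError):
            belief_update_single(belief, 0.66, H)

    @given(b=probs, rho=open_probs)
    @settings(max_examples=200, derandomize=True)
    def test_output_in_unit_interval(self, b, rho):
        for content in (H, NOT_H):
            assert 0.0 <= belief_update_single(b, rho, content) <= 1.0


class TestBeliefUpdateBatch:
    @pytest.mark.parametrize(
        "belief, reports, expected",
        [
            (0.7, [(0.66, H), (0.66, NOT_H)], 0.7),          # symmetric cancellation
            (0.5, [(0.66, H), (0.66, H)], 0.4356 / 0.5512),  # odds (0.66/0.34)^2
            (0.5, [], 0.5),                                  # empty batch identity
        ],
    )
    def test_examples(self, belief, reports, expected):
        assert belief_update_batch(belief, reports) == pytest.approx(expected, abs=1e-12)

    @given(
        b=open_probs,
        rhos=st.lists(open_probs, min_size=1, max_size=6),
        signs=st.lists(st.booleans(), min_size=6, max_size=6),
    )
    @settings(max_examples=150, derandomize=True)
    def test_equals_iterated_single_and_is_order_invariant(self, b, rhos, signs):
        reports = [(r, H if s else NOT_H) for r, s in zip(rhos, signs)]
        batch = belief_update_batch(b, reports)
        iterated = b
        for rho, content in reports:
            iterated = belief_update_single(iterated, rho, content)
        assert batch == pytest.approx(iterated, abs=1e-12)
        assert belief_update_batch(b, list(reversed(reports))) == pytest.approx(
            batch, abs=1e-12
        )


class TestTrustState:
    def test_beta_prior_mean_and_normalisation(self):
        ts = TrustState.beta(2, 1)
        assert ts.kind is TrustKind.DENSITY
        assert ts.mean == pytest.approx(2 / 3, abs=1e-6)
        assert ts.integral() == pytest.approx(1.0, abs=1e-9)

    def test_uniform_prior_mean(self):
        assert TrustState.beta(1, 1).mean == pytest.approx(0.5, abs=1e-9)

    def test_fixed_value_and_bounds(self):
        assert expected_trust(TrustState.fixed(0.66)) == 0.66
        for bad in (0.0, 1.0, -0.2):
            with pytest.raises(ValueError):
                TrustState.fixed(bad)

    def test_negative_density_rejected(self):
        values = np.linspace(-0.5, 1.0, 201)
        with pytest.raises(ValueError):
            TrustState.from_density(values)

    def test_even_grid_rejected(self):
        with pytest.raises(ValueError):
            simpson_weights(200)


class TestTrustUpdate:
    def test_agnostic_content_leaves_density_unchanged(self):
        ts = TrustState.beta(2, 1)
        updated = trust_update(ts, 0.5)
        np.testing.assert_allclose(updated.weights, ts.weights, atol=1e-12)

    @pytest.mark.parametrize(
        "b_c, expected_mean",
        [
            (1.0, 0.75),       # conjugate: Beta(2,1) -> Beta(3,1)
            (0.8, 26 / 36),    # two-component mixture, w = 8/9
            (0.0, 0.5),        # fully incongruent: mass shifts down
        ],
    )
    def test_posterior_mean_closed_form(self, b_c, expected_mean):
        ts = TrustState.beta(2, 1)
        oracle = BetaMixtureOracle(2, 1).update(b_c)
        assert oracle.mean == pytest.approx(expected_mean, abs=1e-12)
        assert trust_update(ts, b_c).mean == pytest.approx(expected_mean, abs=1e-6)

    def test_congruence_direction_moves_trust_mean(self):
        ts = TrustState.beta(2, 1)
        assert trust_update(ts, 0.9).mean > ts.mean - 1e-12
        assert trust_update(ts, 0.9).mean > trust_update(ts, 0.5).mean
        assert trust_update(ts, 0.1).mean < trust_update(ts, 0.5).mean

    def test_ten_updates_match_mixture_oracle(self, rng):
        """Grid posterior tracks the exact Beta-mixture expansion to 1e-6."""
        ts = TrustState.beta(2, 1)
        oracle = BetaMixtureOracle(2, 1)
        for b_c in rng.random(10):
            ts = trust_update(ts, b_c)
            oracle.update(b_c)
            assert ts.mean == pytest.approx(oracle.mean, abs=1e-6)
            assert ts.integral() == pytest.approx(1.0, abs=1e-9)

    def test_fixed_trust_rejected(self):
        with pytest.raises(ValueError):
            trust_update(TrustState.fixed(0.66), 0.8)


class TestPredictiveAndClosedForm:
    @pytest.mark.parametrize(
        "b, rho, expected",
        [(0.5, 0.66, 0.5), (1.0, 0.66, 0.66), (0.8, 2 / 3, 0.6)],
    )
    def test_predictive_report_prob(self, b, rho, expected):
        assert predictive_report_prob(b, TrustState.fixed(rho)) == pytest.approx(
            expected, abs=1e-12
        )

    @pytest.mark.parametrize(
        "n_pos, n_neg, t, prior, expected",
        [
            (5, 5, 0.66, 0.5, 0.5),
            (2, 0, 0.66, 0.5, 0.4356 / 0.5512),
            (0, 1, 0.75, 0.5, 0.25),
        ],
    )
    def test_closed_form_examples(self, n_pos, n_neg, t, prior, expected):
        assert fixed_trust_belief_closed_form(n_pos, n_neg, t, prior) == pytest.approx(
            expected, abs=1e-12
        )

    @given(
        n_pos=st.integers(0, 12),
        n_neg=st.integers(0, 12),
        t=open_probs,
        prior=open_probs,
    )
    @settings(max_examples=100, derandomize=True)
    def test_closed_form_equals_batch(self, n_pos, n_neg, t, prior):
        reports = [(t, H)] * n_pos + [(t, NOT_H)] * n_neg
        assert fixed_trust_belief_closed_form(n_pos, n_neg, t, prior) == pytest.approx(
            belief_update_batch(prior, reports), abs=1e-12
        )


class TestMartingales:
    def test_belief_martingale_exact(self, rng):
        """E over the agent's predictive distribution of the one-report
        posterior equals the prior belief (analytic identity)."""
        for b, rho in zip(rng.random(200), 0.02 + 0.96 * rng.random(200)):
            ts = TrustState.fixed(rho)
            p = predictive_report_prob(b, ts)
            post = p * belief_update_single(b, rho, H) + (1 - p) * belief_update_single(
                b, rho, NOT_H
            )
            assert post == pytest.approx(b, abs=1e-12)

    def test_trust_mean_martingale_on_grid(self, rng):
        """Expected posterior trust mean under the predictive distribution
        equals the prior trust mean, to grid tolerance."""
        ts = TrustState.beta(2, 1)
        for b in rng.random(50):
            p = predictive_report_prob(b, ts)
            up = trust_update(ts, b)          # report asserts h, content prob b
            down = trust_update(ts, 1.0 - b)  # report asserts not-h
            assert p * up.mean + (1 - p) * down.mean == pytest.approx(
                ts.mean, abs=1e-8
            )
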