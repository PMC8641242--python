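"""Exact identities of the finite-state free-energy engine."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from collative.discrete import (
    DiscreteDistribution,
    DiscreteGenerativeModel,
    ImpossibleObservationError,
    SupportMismatchError,
    decompose_free_energy,
    entropy,
    exact_posterior,
    free_energy,
    kl_divergence,
    model_from_json,
    model_to_json,
    predictive_cross_entropy,
    random_distribution,
    random_model,
    uncertainty_reduction,
)

LN06 = -math.log(0.6)


def random_case(seed):
    """A random (model, q, x) triple with everything strictly positive a.s."""
    rng = np.random.default_rng(seed)
    k = int(rng.integers(2, 6))
    s = int(rng.integers(2, 6))
    model = random_model(k, s, rng)
    q = random_distribution(k, rng)
    x = int(rng.integers(s))
    return model, q, x


class TestDistributions:
    def test_rejects_negative_and_unnormalized(self):
        with pytest.raises(ValueError):
            DiscreteDistribution(np.array([0.7, -0.3, 0.6]))
        with pytest.raises(ValueError):
            DiscreteDistribution(np.array([0.5, 0.4]))

    def test_kl_is_infinite_off_support(self):
        assert kl_divergence([0.5, 0.5], [1.0, 0.0]) == math.inf

    def test_kl_support_mismatch(self):
        with pytest.raises(SupportMismatchError):
            kl_divergence([0.5, 0.5], [0.2, 0.3, 0.5])

    def test_entropy_handles_zero_mass(self):
        assert entropy(np.array([1.0, 0.0])) == 0.0


class TestPosterior:
    def test_hand_bayes(self, coin_model):
        post = exact_posterior(coin_model, 0)
        np.testing.assert_allclose(post.probs, [2 / 3, 1 / 3], atol=1e-12)

    def test_symbol_by_label(self, coin_model):
        post = exact_posterior(coin_model, "s0")
        np.testing.assert_allclose(post.probs, [2 / 3, 1 / 3], atol=1e-12)

    def test_uninformative_column_returns_prior(self):
        model = DiscreteGenerativeModel([0.3, 0.7], [[0.5, 0.5], [0.5, 0.5]])
        post = exact_posterior(model, 0)
        np.testing.assert_allclose(post.probs, model.prior.probs, atol=1e-12)

    def test_degenerate_prior_is_fixed_point(self):
        model = DiscreteGenerativeModel([1.0, 0.0], [[0.9, 0.1], [0.2, 0.8]])
        post = exact_posterior(model, 0)
        np.testing.assert_allclose(post.probs, [1.0, 0.0], atol=1e-15)

    def test_impossible_observation(self):
        model = DiscreteGenerativeModel([1.0, 0.0], [[1.0, 0.0], [0.0, 1.0]])
        with pytest.raises(ImpossibleObservationError):
            exact_posterior(model, 1)


class TestFreeEnergy:
    def test_at_posterior_equals_surprisal(self, coin_model):
        post = exact_posterior(coin_model, 0)
        assert free_energy(coin_model, post, 0) == pytest.approx(LN06, abs=1e-12)

    def test_at_prior_adds_kl_to_posterior(self, coin_model):
        # KL((.5,.5) ‖ (2/3,1/3)) = 0.5 ln(9/8) ≈ 0.0588915
        expected = LN06 + 0.5 * math.log(1.125)
        assert free_energy(coin_model, coin_model.prior, 0) == pytest.approx(
            expected, abs=1e-12
        )

    def test_single_cause_model(self):
        model = DiscreteGenerativeModel([1.0], [[0.3, 0.7]])
        for q in ([1.0],):
            assert free_energy(model, q, 1) == pytest.approx(-math.log(0.7), abs=1e-12)

    def test_mass_off_joint_support_gives_infinity(self):
        model = DiscreteGenerativeModel([0.5, 0.5], [[1.0, 0.0], [0.0, 1.0]])
        assert free_energy(model, [0.5, 0.5], 0) == math.inf

    def test_support_mismatch(self, coin_model):
        with pytest.raises(SupportMismatchError):
            free_energy(coin_model, [0.2, 0.3, 0.5], 0)

    def test_random_q_never_beats_posterior(self, coin_model, rng):
        """Brute force over 10,000 recognition densities on the simplex."""
        post = exact_posterior(coin_model, 0)
        f_star = free_energy(coin_model, post, 0)
        qs = rng.dirichlet(np.ones(2), size=10_000)
        joint = coin_model.joint()[:, 0]
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = qs * (np.log(qs) - np.log(joint)[None, :])
        terms = np.where(qs > 0, terms, 0.0)
        f_all = terms.sum(axis=1)
        assert np.all(f_all >= f_star - 1e-12)


class TestDecomposition:
    def test_posterior_components(self, coin_model):
        post = exact_posterior(coin_model, 0)
        rec = decompose_free_energy(coin_model, post, 0)
        assert rec.bayesian_surprise == pytest.approx(0.0566330, abs=1e-6)
        assert rec.inverse_accuracy == pytest.approx(0.4541926, abs=1e-6)
        assert rec.free_energy == pytest.approx(LN06, abs=1e-12)

    def test_prior_recognition_has_zero_surprise(self, coin_model):
        rec = decompose_free_energy(coin_model, coin_model.prior, 0)
        assert rec.bayesian_surprise == 0.0

    @pytest.mark.parametrize("seed", range(100))
    def test_both_decompositions_match_direct_sum(self, seed):
        model, q, x = random_case(seed)
        rec = decompose_free_energy(model, q, x)
        direct = free_energy(model, q, x)
        assert rec.kl_to_posterior + rec.surprisal == pytest.approx(direct, abs=1e-10)
        assert rec.bayesian_surprise + rec.inverse_accuracy == pytest.approx(
            direct, abs=1e-10
        )
        assert rec.kl_to_posterior >= 0
        assert rec.bayesian_surprise >= 0


class TestUncertainty:
    def test_hand_values(self, coin_model):
        rec = uncertainty_reduction(coin_model, 0)
        assert rec.u_pri == pytest.approx(0.5697171, abs=1e-6)
        assert rec.u_post == pytest.approx(0.4541926, abs=1e-6)
        assert rec.reduction == pytest.approx(0.1155245, abs=1e-6)

    def test_uninformative_observation_reduces_nothing(self):
        model = DiscreteGenerativeModel([0.3, 0.7], [[0.5, 0.5], [0.5, 0.5]])
        rec = uncertainty_reduction(model, 0)
        assert rec.reduction == pytest.approx(0.0, abs=1e-12)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_reduction_is_symmetrized_kl_and_nonnegative(self, seed):
        model, _, x = random_case(seed)
        rec = uncertainty_reduction(model, x)
        post = exact_posterior(model, x)
        sym = kl_divergence(model.prior, post) + kl_divergence(post, model.prior)
        assert rec.reduction >= -1e-12
        assert rec.reduction == pytest.approx(sym, abs=1e-10)
        # predictive bound and Jensen under the prior
        assert rec.u_post >= rec.u_star - 1e-12
        prior_pred = -math.log(model.marginal_likelihood(x))
        assert rec.u_pri >= prior_pred - 1e-12


class TestPredictiveCrossEntropy:
    def test_matched_predictive_attains_entropy_floor(self):
        counts = np.array([3, 1, 4])
        f = counts / counts.sum()
        rec = predictive_cross_entropy(DiscreteDistribution(f), counts)
        assert rec.kl_to_empirical == pytest.approx(0.0, abs=1e-12)
        assert rec.cross_entropy == pytest.approx(rec.empirical_entropy, abs=1e-12)

    def test_single_observation_total(self):
        rec = predictive_cross_entropy(DiscreteDistribution([0.6, 0.4]), [1, 0])
        assert rec.u_star_total == pytest.approx(LN06, abs=1e-12)

    def test_zero_predictive_at_observed_symbol(self):
        rec = predictive_cross_entropy(DiscreteDistribution([1.0, 0.0]), [1, 1])
        assert rec.cross_entropy == math.inf

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_cross_entropy_bounded_below_by_entropy(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(2, 6))
        pred = random_distribution(k, rng)
        counts = rng.integers(0, 10, size=k)
        if counts.sum() == 0:
            counts[0] = 1
        rec = predictive_cross_entropy(pred, counts)
        assert rec.cross_entropy >= rec.empirical_entropy - 1e-12
        assert rec.u_star_total == pytest.approx(
            counts.sum() * rec.cross_entropy, rel=1e-12
        )


class TestJsonRoundTrip:
    def test_round_trip(self, coin_model):
        text = model_to_json(coin_model)
        back = model_from_json(text)
        np.testing.assert_allclose(back.prior.probs, coin_model.prior.probs)
        np.testing.assert_allclose(back.likelihood, coin_model.likelihood)
        assert back.symbol_labels == coin_model.symbol_labels

    def test_bad_row_is_named(self):
        text = (
            '{"causes": ["a", "b"], "symbols": ["x", "y"],'
            ' "prior": [0.5, 0.5],'
            ' "likelihood": [[0.5, 0.5], [0.7, 0.2]]}'
        )
        with pytest.raises(ValueError, match=r"row 1 \(cause 'b'\)"):
            model_from_json(text)

    def test_missing_field(self):
        with pytest.raises(ValueError, match="likelihood"):
            model_from_json('{"prior": [1.0]}')
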