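"""Dirichlet-process binomial mixture: mask rule, likelihood, sampler."""

import math

import numpy as np
import pytest

from pyrclone.dp_mixture import (
    DirichletProcessBinomialMixture,
    PosteriorSamples,
    crp_expected_k,
    log_likelihood,
    posterior_predictive,
    progenitor_count_distribution,
    selection_mask,
)
from pyrclone.lineage import GENERATION_ORDER
from pyrclone.stats import laminar_fractions
from pyrclone.synthetic import generate_occupancy_dataset


def gen_row(l23, l4, l5, l6):
    """Row in generation order (VI, V, IV, II/III) from named counts."""
    return [l6, l5, l4, l23]


class TestSelectionMask:
    @pytest.mark.parametrize(
        "row, expected",
        [
            # deep-restricted: terminal superficial zeros censored
            (gen_row(0, 0, 2, 3), gen_row(0, 0, 1, 1)),
            # II/III's zero is terminal; V's zero is interior (kept)
            (gen_row(0, 1, 0, 2), gen_row(0, 1, 1, 1)),
            (gen_row(1, 1, 1, 1), gen_row(1, 1, 1, 1)),
            # superficial-restricted: nothing to censor
            (gen_row(2, 1, 0, 0), gen_row(1, 1, 1, 1)),
        ],
    )
    def test_censoring_rule(self, row, expected):
        assert selection_mask(np.array([row])).tolist() == [expected]

    def test_zero_only_where_count_zero(self):
        rng = np.random.default_rng(0)
        S = rng.integers(0, 4, size=(200, 4))
        sigma = selection_mask(S)
        assert np.all(S[sigma == 0] == 0)

    def test_empty_row_fully_masked_with_warning(self):
        with pytest.warns(UserWarning, match="empty"):
            sigma = selection_mask(np.array([[0, 0, 0, 0], [1, 0, 0, 0]]))
        assert sigma[0].tolist() == [0, 0, 0, 0]
        assert sigma[1].tolist() == [1, 0, 0, 0]


class TestLogLikelihood:
    def test_frozen_uniform_case(self):
        """One lineage (1,1,1,1), p = 0.5 everywhere, N_max = 20: every layer
        contributes 20 log(1/2), so the total is 80 log(1/2)."""
        S = np.ones((1, 4), dtype=int)
        sigma = np.ones((1, 4), dtype=int)
        value = log_likelihood(
            S, sigma, t=np.array([0]), p=np.array([[0.5] * 4]),
            f=np.array([1.0]), n_max=20,
        )
        assert value == pytest.approx(80 * math.log(0.5), rel=1e-12)

    def test_matches_direct_enumeration_oracle(self):
        """Exact agreement with a literal term-by-term evaluation of the
        masked product-of-binomials likelihood."""
        rng = np.random.default_rng(5)
        for _ in range(20):
            n, k, n_max = 6, 2, 8
            S = rng.integers(0, n_max + 1, size=(n, 4))
            sigma = rng.integers(0, 2, size=(n, 4))
            sigma[S > 0] = 1
            t = rng.integers(0, k, size=n)
            p = rng.uniform(0.05, 0.95, size=(k, 4))
            f = rng.dirichlet(np.ones(k))
            expected = 0.0
            for typ in range(k):
                expected += np.sum(t == typ) * math.log(f[typ])
            for i in range(n):
                for j in range(4):
                    if sigma[i, j]:
                        expected += S[i, j] * math.log(p[t[i], j])
                        expected += (n_max - S[i, j]) * math.log(1 - p[t[i], j])
            assert log_likelihood(S, sigma, t, p, f, n_max) == pytest.approx(
                expected, rel=1e-10
            )

    def test_all_masked_leaves_only_frequency_term(self):
        S = np.array([[3, 0, 1, 2]])
        sigma = np.zeros((1, 4), dtype=int)
        assert log_likelihood(
            S, sigma, np.array([0]), np.array([[0.5] * 4]), np.array([1.0]), 20
        ) == pytest.approx(0.0)

    def test_extreme_probabilities(self):
        S = np.full((1, 4), 20)
        sigma = np.ones((1, 4), dtype=int)
        t, f = np.array([0]), np.array([1.0])
        # p = 1 with saturated counts: each factor is 1, log contribution 0
        assert log_likelihood(S, sigma, t, np.ones((1, 4)), f, 20) == 0.0
        # p = 1 contradicted by a sub-maximal count: -inf, not an exception
        S2 = np.array([[19, 20, 20, 20]])
        assert log_likelihood(S2, sigma, t, np.ones((1, 4)), f, 20) == -np.inf

    def test_label_exchangeability(self):
        rng = np.random.default_rng(2)
        S = rng.integers(0, 10, size=(8, 4))
        sigma = selection_mask(S)
        t = rng.integers(0, 3, size=8)
        p = rng.uniform(0.1, 0.9, size=(3, 4))
        f = rng.dirichlet(np.ones(3))
        base = log_likelihood(S, sigma, t, p, f, 20)
        perm = np.array([2, 0, 1])
        inv = np.argsort(perm)
        assert log_likelihood(S, sigma, perm[t], p[inv], f[inv], 20) == pytest.approx(
            base, rel=1e-12
        )


class TestSampler:
    def test_determinism_under_seed(self):
        S, _ = generate_occupancy_dataset(1, [[0.3] * 4], [1.0], n=20, seed=3)
        fits = [
            DirichletProcessBinomialMixture(
                n_draws=50, burn_in=10, random_state=99
            ).fit(S)
            for _ in range(2)
        ]
        assert np.array_equal(fits[0].samples_.k, fits[1].samples_.k)
        assert np.array_equal(fits[0].samples_.t, fits[1].samples_.t)
        assert np.allclose(
            fits[0].samples_.log_likelihood, fits[1].samples_.log_likelihood
        )

    def test_single_lineage_always_one_type(self):
        model = DirichletProcessBinomialMixture(
            n_draws=100, burn_in=10, random_state=0
        ).fit(np.array([[2, 3, 1, 0]]))
        assert set(model.samples_.k.tolist()) == {1}

    def test_identical_extreme_rows_coassigned(self):
        """Two saturated rows: the Beta-binomial evidence for sharing one
        type overwhelms the CRP prior's 1/2 split probability."""
        S = np.full((2, 4), 20)
        model = DirichletProcessBinomialMixture(
            n_draws=400, burn_in=100, random_state=1
        ).fit(S)
        together = np.mean(model.samples_.t[:, 0] == model.samples_.t[:, 1])
        assert together > 0.95

    def test_conjugate_posterior_mean_single_type(self):
        """With the concentration driven to zero the chain stays at K = 1 and
        the sampled occupancy probabilities must average to the closed-form
        Beta posterior mean."""
        S, _ = generate_occupancy_dataset(
            1, [[0.15, 0.4, 0.6, 0.85]], [1.0], n=30, seed=8
        )
        a = b = 1.0
        model = DirichletProcessBinomialMixture(
            n_draws=2000, burn_in=200, alpha=1e-9, beta_a=a, beta_b=b,
            random_state=4,
        ).fit(S)
        assert set(model.samples_.k.tolist()) == {1}
        sigma = model.mask_
        post_mean = (a + (sigma * S).sum(axis=0)) / (
            a + b + (sigma * 20).sum(axis=0)
        )
        sampled = np.mean([p[0] for p in model.samples_.p], axis=0)
        assert np.allclose(sampled, post_mean, atol=0.02)

    def test_homogeneous_data_modal_k_is_one(self):
        S, _ = generate_occupancy_dataset(1, [[0.3, 0.3, 0.3, 0.3]], [1.0],
                                          n=100, seed=13)
        model = DirichletProcessBinomialMixture(
            n_draws=300, burn_in=100, random_state=5
        ).fit(S)
        assert model.n_types_ == 1

    def test_validation_errors(self):
        with pytest.raises(ValueError, match="N_max"):
            DirichletProcessBinomialMixture(n_max=20).fit(np.array([[25, 0, 0, 0]]))
        with pytest.raises(ValueError):
            DirichletProcessBinomialMixture(alpha=-1).fit(np.ones((2, 4), dtype=int))
        with pytest.raises(ValueError):
            DirichletProcessBinomialMixture().fit(np.ones((2, 5), dtype=int))

    def test_sklearn_param_interface(self):
        model = DirichletProcessBinomialMixture(alpha=2.0)
        assert model.get_params()["alpha"] == 2.0
        model.set_params(n_draws=10)
        assert model.n_draws == 10


class TestPosteriorSummaries:
    @staticmethod
    def _collapsed(p_row):
        return PosteriorSamples(
            k=np.array([1]),
            t=np.array([[0]]),
            p=[np.array([p_row])],
            f=[np.array([1.0])],
            log_likelihood=np.array([0.0]),
            n_max=20,
        )

    def test_count_distribution_examples(self):
        samples = PosteriorSamples(
            k=np.array([1, 1, 2, 2]), t=np.zeros((4, 1), dtype=int),
            p=[np.zeros((1, 4))] * 4, f=[np.ones(1)] * 4,
            log_likelihood=np.zeros(4),
        )
        assert progenitor_count_distribution(samples) == {1: 0.5, 2: 0.5}
        samples.k = np.array([1, 1, 1, 1])
        assert progenitor_count_distribution(samples) == {1: 1.0}

    def test_predictive_collapsed_extremes_filtered_out(self):
        rng = np.random.default_rng(0)
        assert posterior_predictive(self._collapsed([0.0] * 4), 50, (3, 12), rng) == []
        assert posterior_predictive(self._collapsed([1.0] * 4), 50, (3, 12), rng) == []

    def test_predictive_laminar_fractions_match_collapsed_posterior(self):
        p_row = [0.6, 0.3, 0.2, 0.1]  # generation order VI, V, IV, II/III
        rng = np.random.default_rng(1)
        lineages = posterior_predictive(self._collapsed(p_row), 4000, None, rng)
        fractions = laminar_fractions(lineages)  # superficial order
        expected = np.array(p_row[::-1]) / np.sum(p_row)
        assert np.allclose(fractions, expected, atol=0.02)


def test_crp_expected_k_closed_form():
    assert crp_expected_k(1, 1.0) == pytest.approx(1.0)
    assert crp_expected_k(3, 1.0) == pytest.approx(1 + 1 / 2 + 1 / 3)
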