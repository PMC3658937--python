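import math

import numpy as np
import pytest

from pairedbb.betabinom import log_pmf
from pairedbb.data_model import ModelSpec, PairedCountMatrix, ScalingFactors
from pairedbb.estimation import ThetaSample
from pairedbb.inference import (
    compute_posteriors,
    estimate_fdr,
    estimate_priors_bic,
    marginal_log_likelihood,
    marginal_log_likelihood_matrix,
    posterior_probabilities,
    select_at_fdr,
)


def plain_pmf(u, up, pi, phi, L=1.0, Lp=1.0):
    """Non-log beta-binomial pmf via math.gamma — the independent route."""
    p = pi * L / (pi * L + (1 - pi) * Lp)
    comb = math.comb(u + up, u)
    if phi == 0:
        return comb * p ** u * (1 - p) ** up
    a = p * (1 - phi) / phi
    b = (1 - p) * (1 - phi) / phi

    def beta_fn(x, y):
        return math.gamma(x) * math.gamma(y) / math.gamma(x + y)

    return comb * beta_fn(u + a, up + b) / beta_fn(a, b)


def theta(pi, phi, seed=0):
    return ThetaSample(pi=np.asarray(pi, float), phi=np.asarray(phi, float),
                       tuple_ids=[f"s{i}" for i in range(len(pi))], seed=seed)


class TestMarginalLogLikelihood:
    def test_single_theta_entry_reduces_to_plain_likelihood(self, unit_scaling):
        model = ModelSpec("m", [[0, 1], [2, 3]], [None, None])
        u, up = np.array([3, 5, 2, 8]), np.array([4, 4, 7, 1])
        th = [theta([0.4], [0.1]), theta([0.7], [0.05])]
        got = marginal_log_likelihood((u, up), model, th, unit_scaling)
        expected = (sum(log_pmf(int(u[i]), int(up[i]), 0.4, 0.1) for i in (0, 1))
                    + sum(log_pmf(int(u[i]), int(up[i]), 0.7, 0.05) for i in (2, 3)))
        assert got == pytest.approx(expected, abs=1e-10)

    def test_invariant_to_duplicating_theta(self, unit_scaling):
        model = ModelSpec("m", [[0, 1, 2, 3]], [None])
        u, up = np.array([3, 5, 2, 8]), np.array([4, 4, 7, 1])
        th1 = [theta([0.3, 0.6], [0.1, 0.2])]
        th2 = [theta([0.3, 0.6, 0.3, 0.6], [0.1, 0.2, 0.1, 0.2])]
        a = marginal_log_likelihood((u, up), model, th1, unit_scaling)
        b = marginal_log_likelihood((u, up), model, th2, unit_scaling)
        assert a == pytest.approx(b, abs=1e-12)

    def test_matches_brute_force_double_loop(self):
        # 2 sets, 3 pairs, |Theta| = 4: plain-arithmetic product of
        # per-set means, no logs anywhere in the oracle
        model = ModelSpec("m", [[0, 2], [1]], [None, None])
        scaling = ScalingFactors(np.array([1.0, 2.0, 1.5]),
                                 np.array([1.0, 1.0, 0.5]))
        u, up = np.array([4, 0, 7]), np.array([2, 3, 5])
        th = [theta([0.3, 0.5, 0.7, 0.45], [0.05, 0.1, 0.0, 0.2]),
              theta([0.2, 0.6, 0.9, 0.5], [0.0, 0.3, 0.15, 0.08])]
        expected = 1.0
        for q, idx in enumerate(model.sets):
            mean = 0.0
            for pi, phi in zip(th[q].pi, th[q].phi):
                prod = 1.0
                for i in idx:
                    prod *= plain_pmf(int(u[i]), int(up[i]), pi, phi,
                                      scaling.L[i], scaling.L_prime[i])
                mean += prod / len(th[q])
            expected *= mean
        got = marginal_log_likelihood((u, up), model, th, scaling)
        assert got == pytest.approx(math.log(expected), abs=1e-10)

    def test_converges_to_exact_atom_mixture(self, rng):
        # Theta sampled i.i.d. from 3 atoms: the sample-mean approximation
        # converges to the exact atom-weighted integral (law of large numbers)
        model = ModelSpec("m", [[0, 1]], [None], n_pairs=2)
        scaling = ScalingFactors.unit(2)
        u, up = np.array([6, 2]), np.array([3, 5])
        atoms = [(0.3, 0.05), (0.55, 0.2), (0.8, 0.0)]
        weights = np.array([0.5, 0.3, 0.2])
        atom_lik = np.array([
            np.prod([plain_pmf(int(u[i]), int(up[i]), pi, phi)
                     for i in range(2)])
            for pi, phi in atoms
        ])
        exact = float(weights @ atom_lik)
        K = 10000
        draw = rng.choice(3, size=K, p=weights)
        th = [theta([atoms[j][0] for j in draw], [atoms[j][1] for j in draw])]
        got = np.exp(marginal_log_likelihood((u, up), model, th, scaling))
        se = atom_lik.std() / np.sqrt(K)
        assert abs(got - exact) < 3 * se

    def test_empty_theta_rejected(self, unit_scaling):
        model = ModelSpec("m", [[0, 1, 2, 3]], [None])
        with pytest.raises(ValueError):
            marginal_log_likelihood((np.ones(4, int), np.ones(4, int)),
                                    model, [], unit_scaling)


class TestEstimatePriorsBic:
    def test_single_model_gets_prior_one(self):
        m = ModelSpec("only", [[0, 1]], [0.5])
        priors = estimate_priors_bic(np.array([[-1.0], [-2.0]]), [m], 2)
        assert priors == pytest.approx([1.0])

    def test_unanimous_assignment_with_floor(self):
        m0 = ModelSpec("a", [[0, 1]], [None])
        m1 = ModelSpec("b", [[0, 1]], [None])
        ll = np.array([[-1.0, -5.0], [-2.0, -6.0], [-0.5, -9.0]])
        priors = estimate_priors_bic(ll, [m0, m1], 2, floor=1e-3)
        expected = np.array([1.0, 1e-3])
        expected /= expected.sum()
        np.testing.assert_allclose(priors, expected)

    def test_matches_hand_computed_bic(self):
        # k = (0, 1), n_pairs = 4: BIC_M = -2 ll + k log 4
        m0 = ModelSpec("null", [[0, 1, 2, 3]], [0.5])
        m1 = ModelSpec("alt", [[0, 1, 2, 3]], [None])
        log4 = np.log(4.0)
        # tuple 1: alt wins iff -2 ll_alt + log4 < -2 ll_null
        ll = np.array([
            [-5.0, -4.0],              # alt: -8 + log4 < -10 -> alt
            [-5.0, -4.9],              # alt: -9.8 + log4 > -10 -> null
            [-3.0, -3.0],              # tie in ll -> null penalised less
        ])
        priors = estimate_priors_bic(ll, [m0, m1], 4, floor=0.0)
        np.testing.assert_allclose(priors, [2 / 3, 1 / 3])

    def test_parsimony_tie_break(self):
        # identical BIC: the model with fewer free sets wins
        m0 = ModelSpec("free", [[0, 1]], [None])
        m1 = ModelSpec("fixed", [[0, 1]], [0.5])
        ll = np.array([[-2.0 - np.log(2.0) / 2.0 * 0 - 0.0, -2.0]])
        # arrange equal BIC: -2 ll_free + log 2 == -2 ll_fixed
        ll = np.array([[-2.0 + np.log(2.0) / 2.0, -2.0]])
        priors = estimate_priors_bic(ll, [m0, m1], 2, floor=0.0)
        np.testing.assert_allclose(priors, [0.0, 1.0])

    def test_excluded_tuples_do_not_count(self):
        m0 = ModelSpec("a", [[0, 1]], [0.5])
        m1 = ModelSpec("b", [[0, 1]], [None])
        ll = np.array([[0.0, 0.0], [-9.0, -1.0]])
        priors = estimate_priors_bic(ll, [m0, m1], 2,
                                     exclude=[False, True], floor=0.0)
        np.testing.assert_allclose(priors, [1.0, 0.0])


class TestPosteriorProbabilities:
    def test_uniform_under_symmetry(self):
        post = posterior_probabilities(np.full(4, -3.0), np.full(4, 0.25))
        np.testing.assert_allclose(post, 0.25)

    def test_direct_bayes_arithmetic(self):
        post = posterior_probabilities(np.log([0.2, 0.1]), [0.5, 0.5])
        np.testing.assert_allclose(post, [2 / 3, 1 / 3])

    def test_matches_plain_arithmetic_oracle(self, rng):
        for _ in range(20):
            lik = rng.uniform(0.01, 1.0, 5)
            priors = rng.dirichlet(np.ones(5))
            expected = lik * priors / np.sum(lik * priors)
            got = posterior_probabilities(np.log(lik), priors)
            np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_rows_normalised(self, rng):
        ll = rng.normal(-50, 20, size=(30, 4))
        post = posterior_probabilities(ll, np.full(4, 0.25))
        np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-10)

    def test_unnormalised_priors_rejected(self):
        with pytest.raises(ValueError):
            posterior_probabilities(np.array([-1.0, -2.0]), [0.5, 0.4])

    def test_all_impossible_rejected(self):
        with pytest.raises(ValueError):
            posterior_probabilities(np.array([-np.inf, -np.inf]), [0.5, 0.5])


class TestFdr:
    def test_certain_calls_have_zero_fdr(self):
        res = estimate_fdr(np.ones(5))
        np.testing.assert_allclose(res.fdr, 0.0)

    def test_printed_estimator_arithmetic(self):
        res = estimate_fdr(np.array([0.99, 0.95, 0.90]))
        # ranked list is already sorted: FDR at m=2 is (0.01 + 0.05)/2
        assert res.fdr[1] == pytest.approx(0.03)
        assert res.fdr[2] == pytest.approx((0.01 + 0.05 + 0.10) / 3)

    def test_monotone_along_ranking(self, rng):
        post = rng.uniform(0, 1, 200)
        res = estimate_fdr(post)
        ranked = res.fdr[res.order]
        assert np.all(np.diff(ranked) >= -1e-12)

    def test_tie_break_by_tuple_id(self):
        res = estimate_fdr(np.array([0.5, 0.5]), tuple_ids=["b", "a"])
        assert res.rank[1] == 1  # "a" ranks before "b" at equal posterior

    def test_selection_at_threshold(self):
        res = estimate_fdr(np.array([0.99, 0.95, 0.90]))
        # top-2 FDR 0.03 <= 0.05 < top-3 FDR 0.0533
        assert sorted(select_at_fdr(res, 0.05)) == [0, 1]

    def test_selection_boundaries(self):
        assert len(select_at_fdr(estimate_fdr(np.array([0.99, 0.5])), 0.0)) == 0
        sel = select_at_fdr(estimate_fdr(np.array([1.0, 0.5])), 0.0)
        assert list(sel) == [0]
        assert len(select_at_fdr(estimate_fdr(np.full(4, 0.5)), 0.05)) == 0


class TestComputePosteriors:
    def test_all_zero_tuples_get_equal_posteriors(self, unit_scaling):
        counts = PairedCountMatrix(
            ["live", "dead"], [[5, 9, 2, 4], [0, 0, 0, 0]],
            [[5, 1, 8, 4], [0, 0, 0, 0]], ["p1", "p2", "p3", "p4"])
        models = [ModelSpec("null", [[0, 1, 2, 3]], [0.5]),
                  ModelSpec("alt", [[0, 1, 2, 3]], [None])]
        th = {"null": [theta([0.5, 0.5], [0.0, 0.1])],
              "alt": [theta([0.3, 0.8], [0.0, 0.1])]}
        table = compute_posteriors(counts, models, th, unit_scaling)
        np.testing.assert_allclose(table.posteriors[1], 0.5)
        np.testing.assert_allclose(table.posteriors.sum(axis=1), 1.0,
                                   atol=1e-10)
        assert table.priors.sum() == pytest.approx(1.0)

    def test_output_frame_has_all_columns(self, unit_scaling):
        counts = PairedCountMatrix(["a"], [[5, 9, 2, 4]], [[5, 1, 8, 4]],
                                   ["p1", "p2", "p3", "p4"])
        models = [ModelSpec("null", [[0, 1, 2, 3]], [0.5])]
        th = {"null": [theta([0.5], [0.1])]}
        frame = compute_posteriors(counts, models, th, unit_scaling).to_frame()
        assert {"null_loglik", "null_posterior", "null_fdr",
                "null_rank"} <= set(frame.columns)
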