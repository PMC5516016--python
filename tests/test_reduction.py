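"""Bayesian model reduction, search, family probabilities, model averaging."""

import numpy as np
import pytest
from scipy import integrate, stats

from visdcm.inversion import InversionOptions, fit_forward
from visdcm.posterior import GaussianPosterior, PriorSpec
from visdcm.reduction import (bayesian_model_average, bayesian_model_reduction,
                              family_posterior_probability,
                              search_reduced_models)

from conftest import make_linear_problem


class TestBMR:
    def test_identity_reduction_changes_nothing(self):
        post = GaussianPosterior(["x", "y"], np.array([0.5, -0.2]),
                                 np.array([[0.04, 0.01], [0.01, 0.09]]),
                                 free_energy=-12.0)
        prior = PriorSpec(["x", "y"], np.zeros(2), np.ones(2))
        red, df = bayesian_model_reduction(post, prior, prior)
        assert df == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(red.mean, post.mean)
        np.testing.assert_allclose(red.cov, post.cov)

    def test_one_dimensional_quadrature_oracle(self):
        """delta_F equals log int q(x) p_red(x)/p(x) dx (numerical)."""
        post = GaussianPosterior(["x"], np.array([0.8]), np.array([[0.1]]))
        prior = PriorSpec(["x"], np.zeros(1), np.ones(1))
        clamp = 1e-4   # wide enough for quadrature to resolve the spike
        reduced = PriorSpec(["x"], np.zeros(1), np.full(1, clamp))
        red, df = bayesian_model_reduction(post, prior, reduced)

        def integrand(x):
            return (stats.norm.pdf(x, 0.8, np.sqrt(0.1))
                    * stats.norm.pdf(x, 0.0, np.sqrt(clamp))
                    / stats.norm.pdf(x, 0.0, 1.0))

        val, _ = integrate.quad(integrand, -0.5, 0.5, limit=400)
        assert df == pytest.approx(np.log(val), abs=1e-3)

    def test_clamping_drives_posterior_mean_to_zero(self):
        post = GaussianPosterior(["x"], np.array([0.8]), np.array([[0.1]]))
        prior = PriorSpec(["x"], np.zeros(1), np.ones(1))
        red, _ = bayesian_model_reduction(post, prior, prior.switch_off(["x"]))
        assert abs(red.mean[0]) < 1e-3

    def test_matches_direct_inversion_of_reduced_model(self):
        """The module's master oracle: on a linear-Gaussian model, reducing
        the full posterior equals inverting the reduced model directly."""
        prob = make_linear_problem(seed=1, theta=(0.9, 0.0, -0.5))
        opts = InversionOptions(estimate_noise=False, log_precision=prob["lam"])
        full = fit_forward(prob["forward"], prob["y"], prob["prior"], opts)
        reduced_prior = prob["prior"].switch_off(["b"])
        direct = fit_forward(prob["forward"], prob["y"], reduced_prior, opts)
        red, df = bayesian_model_reduction(full, prob["prior"], reduced_prior)
        assert df == pytest.approx(direct.free_energy - full.free_energy, abs=1e-3)
        np.testing.assert_allclose(red.mean, direct.mean, atol=1e-4)

    def test_degenerate_precision_reported(self):
        post = GaussianPosterior(["x"], np.array([0.0]), np.array([[10.0]]))
        prior = PriorSpec(["x"], np.zeros(1), np.full(1, 1e-3))
        wider = PriorSpec(["x"], np.zeros(1), np.full(1, 10.0))
        with pytest.raises(np.linalg.LinAlgError):
            bayesian_model_reduction(post, prior, wider)


class TestSearch:
    def _fitted(self, seed=1, theta=(0.9, 0.0, -0.5)):
        prob = make_linear_problem(seed=seed, theta=theta)
        opts = InversionOptions(estimate_noise=False, log_precision=prob["lam"])
        return fit_forward(prob["forward"], prob["y"], prob["prior"], opts), prob

    def test_single_parameter_gives_two_models(self):
        full, prob = self._fitted()
        space = search_reduced_models(full, prob["prior"], ["a"])
        assert space.n_models == 2
        on_all = space.indicators.all(axis=1)
        assert space.delta_f[on_all][0] == pytest.approx(0.0, abs=1e-12)

    def test_exhaustive_enumeration_and_best_model(self):
        prob = make_linear_problem(seed=3, names=list("abcd"),
                                   theta=(0.8, 0.0, -0.6, 0.0))
        opts = InversionOptions(estimate_noise=False, log_precision=prob["lam"])
        full = fit_forward(prob["forward"], prob["y"], prob["prior"], opts)
        space = search_reduced_models(full, prob["prior"], list("abcd"))
        assert space.n_models == 16 and space.exhaustive
        assert np.all(space.delta_f[space.best()] >= space.delta_f)

    def test_greedy_never_beats_exhaustive(self):
        prob = make_linear_problem(
            seed=4, n=120, names=[f"p{i}" for i in range(10)],
            theta=(0.7, 0.0, -0.5, 0.0, 0.3, 0.0, 0.0, 0.4, 0.0, -0.2))
        opts = InversionOptions(estimate_noise=False, log_precision=prob["lam"])
        full = fit_forward(prob["forward"], prob["y"], prob["prior"], opts)
        exhaustive = search_reduced_models(full, prob["prior"], prob["prior"].names)
        greedy = search_reduced_models(full, prob["prior"], prob["prior"].names,
                                       max_exhaustive_k=2)
        assert not greedy.exhaustive
        assert greedy.delta_f.max() <= exhaustive.delta_f.max() + 1e-9

    def test_truly_zero_parameter_is_switched_off(self):
        """Models pruning a null parameter win the search in most replicates."""
        wins = 0
        for seed in range(20):
            full, prob = self._fitted(seed=100 + seed, theta=(0.9, 0.0, -0.5))
            space = search_reduced_models(full, prob["prior"], prob["prior"].names)
            best = space.indicators[space.best()]
            wins += int(not best[1])   # parameter "b" generated at 0
        assert wins >= 16

    def test_empty_switchable_rejected(self):
        full, prob = self._fitted()
        with pytest.raises(ValueError):
            search_reduced_models(full, prob["prior"], [])


class TestFamilyProbability:
    def _space(self, delta_f, indicators, names):
        k = len(names)
        post = GaussianPosterior(names, np.zeros(k), np.eye(k))
        prior = PriorSpec(names, np.zeros(k), np.ones(k))
        from visdcm.reduction import ModelSpace
        return ModelSpace(list(names), np.asarray(indicators, bool),
                          np.asarray(delta_f, float), post, prior)

    def test_equal_evidence_gives_half(self):
        space = self._space([0.0, 0.0], [[True], [False]], ["x"])
        assert family_posterior_probability(space, "x") == pytest.approx(0.5)

    def test_always_on_gives_one(self):
        space = self._space([0.0, -1.0], [[True], [True]], ["x"])
        assert family_posterior_probability(space, "x") == pytest.approx(1.0)

    def test_softmax_arithmetic(self):
        space = self._space([0.0, -3.0], [[True], [False]], ["x"])
        assert family_posterior_probability(space, "x") == pytest.approx(
            1.0 / (1.0 + np.exp(-3.0)), abs=1e-12)

    def test_complement_sums_to_one_and_shift_invariance(self):
        rng = np.random.default_rng(0)
        df = rng.normal(0, 2, 8)
        ind = np.array([[(m >> j) & 1 == 0 for j in range(3)] for m in range(8)])
        names = ["x", "y", "z"]
        space = self._space(df, ind, names)
        for nm in names:
            pp_on = family_posterior_probability(space, nm)
            flipped = self._space(df, ~ind, names)
            pp_off_of_flipped = family_posterior_probability(flipped, nm)
            assert pp_on + pp_off_of_flipped == pytest.approx(1.0)
        shifted = self._space(df + 17.3, ind, names)
        for nm in names:
            assert family_posterior_probability(shifted, nm) == pytest.approx(
                family_posterior_probability(space, nm))


class TestBMA:
    def test_single_model_returned_unchanged(self):
        full, prob = make_fitted_single()
        space = search_reduced_models(full, prob["prior"], ["a"])
        # restrict to just the full model
        from visdcm.reduction import ModelSpace
        solo = ModelSpace(space.switchable, space.indicators[:1],
                          space.delta_f[:1], full, prob["prior"])
        bma = bayesian_model_average(solo)
        np.testing.assert_allclose(bma.mean, full.mean, atol=1e-10)
        np.testing.assert_allclose(bma.cov, full.cov, atol=1e-10)

    def test_equal_evidence_mixture_averages_means(self):
        names = ["x"]
        post = GaussianPosterior(names, np.array([1.0]), np.array([[0.5]]))
        prior = PriorSpec(names, np.zeros(1), np.ones(1))
        from visdcm.reduction import ModelSpace
        space = ModelSpace(names, np.array([[True], [False]]),
                           np.zeros(2), post, prior)
        bma = bayesian_model_average(space)
        m_on = space.posterior(0).mean[0]
        m_off = space.posterior(1).mean[0]
        assert bma.mean[0] == pytest.approx((m_on + m_off) / 2)

    def test_mixture_covariance_dominates_within_model(self):
        """Law of total variance: BMA covariance >= weighted within-model
        covariance (Loewner order)."""
        full, prob = make_fitted_single()
        space = search_reduced_models(full, prob["prior"], prob["prior"].names)
        bma = bayesian_model_average(space)
        from scipy.special import softmax
        w = softmax(space.delta_f)
        within = sum(wi * space.posterior(i).cov for i, wi in enumerate(w))
        eigs = np.linalg.eigvalsh(bma.cov - within)
        assert eigs.min() >= -1e-10


def make_fitted_single(seed=1):
    prob = make_linear_problem(seed=seed)
    opts = InversionOptions(estimate_noise=False, log_precision=prob["lam"])
    return fit_forward(prob["forward"], prob["y"], prob["prior"], opts), prob
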