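import numpy as np
import pandas as pd
import pytest
from scipy.stats import beta as beta_dist, multivariate_normal, norm

from prodsir import inference as inf
from prodsir import production_model as pm
from prodsir import synthetic_data as sd


def random_psd(n, rng, scale=0.05):
    B = rng.normal(size=(n, n)) * scale
    return B @ B.T + np.eye(n) * scale**2


@pytest.fixture(scope="module")
def small_bundle():
    """Synthetic data bundle shared by SIR smoke tests."""
    from prodsir import survey_index as si

    ds = sd.generate_assessment_dataset(sd.TruthBundle(seed=42))
    model = si.fit_daily_model(ds.flight_counts)
    residence = si.discretize_residence(60.0, 8.66)
    idx = si.index_covariance(model, residence, n_rep=300, seed=1)
    bundle = inf.DataBundle(
        catch_bounds=ds.catch_bounds,
        index_years=idx.years,
        index_a=idx.a,
        index_sigma=idx.sigma,
        absolute_estimate=ds.absolute_estimate,
        absolute_se=ds.absolute_se,
    )
    return ds, bundle


class TestDistributions:
    def test_from_dict(self):
        d = inf.distribution_from_dict({"dist": "uniform", "low": 0, "high": 0.11})
        assert d == inf.Uniform(0, 0.11)

    def test_unknown_tag_rejected(self):
        with pytest.raises(ValueError, match="unknown distribution"):
            inf.distribution_from_dict({"dist": "gamma", "a": 1})

    def test_malformed_spec_rejected(self):
        with pytest.raises(ValueError, match="malformed"):
            inf.distribution_from_dict({"dist": "uniform", "low": 0})

    def test_truncated_lognormal_support(self):
        d = inf.TruncatedLogNormal(-2.67, 0.5, 0.02, 0.11)
        x = d.sample(5000, np.random.default_rng(0))
        assert x.min() >= 0.02 and x.max() <= 0.11


class TestSamplePriors:
    def test_base_supports(self):
        draws = inf.sample_priors(inf.base_priors(), 5000, seed=0)
        assert draws["r_max"].between(0, 0.11).all()
        assert draws["p_msy"].between(0.5, 0.8).all()
        assert draws["n_recent"].between(100, 10_000).all()
        assert draws["sigma2"].between(6.5e-5, 6.5e-4).all()
        assert draws["pi"].between(0, 1).all()
        assert (draws["beta"] == 0).all()
        assert (draws["tau2"] == 0).all()

    def test_slr_prior_means(self):
        draws = inf.sample_priors(inf.base_priors(), 40_000, seed=1)
        assert draws["slr1"].mean() == pytest.approx(1.6, abs=0.002)
        assert draws["slr2"].mean() == pytest.approx(1.09, abs=0.002)
        assert draws["slr1"].std() == pytest.approx(0.04, abs=0.002)

    def test_seed_reproducible(self):
        a = inf.sample_priors(inf.base_priors(), 100, seed=7)
        b = inf.sample_priors(inf.base_priors(), 100, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_overrides_validated(self):
        with pytest.raises(ValueError, match="unknown prior keys"):
            inf.base_priors().with_overrides(nope=inf.Fixed(1))


class TestAnalyticQ:
    def test_exact_recovery_zero_residuals(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = rng.integers(3, 12)
            N = rng.uniform(100, 10_000, n)
            beta = rng.uniform(-0.2, 0.2)
            q = rng.uniform(0.01, 1.0)
            A = q * N ** (1 + beta)
            sigma = random_psd(n, rng)
            assert inf.analytic_q(A, N, sigma, beta) == pytest.approx(q, rel=1e-9)

    def test_geometric_mean_identity_case(self):
        # sigma = I, beta = 0, ratios (2, 8) -> geometric mean 4
        N = np.array([1.0, 1.0])
        A = np.array([2.0, 8.0])
        assert inf.analytic_q(A, N, np.eye(2)) == pytest.approx(4.0)

    def test_profile_maximum_property(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            n = rng.integers(3, 10)
            N = rng.uniform(100, 5000, n)
            A = rng.uniform(50, 5000, n)
            sigma = random_psd(n, rng)
            qhat = inf.analytic_q(A, N, sigma)
            def ll(q):
                return multivariate_normal(np.log(q * N), sigma).logpdf(np.log(A))
            assert ll(qhat) >= ll(qhat * 1.05) - 1e-12
            assert ll(qhat) >= ll(qhat * 0.95) - 1e-12

    def test_singular_sigma_rejected(self):
        with pytest.raises(ValueError):
            inf.analytic_q(np.array([1.0, 2.0]), np.array([1.0, 1.0]), np.zeros((2, 2)))

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            inf.analytic_q(np.array([0.0, 2.0]), np.array([1.0, 1.0]), np.eye(2))


class TestLoglikIndex:
    def test_perfect_fit_equals_mvn_at_mean(self):
        N = np.array([1000.0, 2000.0, 1500.0])
        A = 0.3 * N
        s2 = 0.02
        ll = inf.loglik_index(A, N, s2 * np.eye(3))
        expect = multivariate_normal(np.log(A), s2 * np.eye(3)).logpdf(np.log(A))
        assert ll == pytest.approx(expect)

    def test_misfit_decreases_loglik(self):
        N = np.array([1000.0, 2000.0])
        sigma = 0.05 * np.eye(2)
        base = inf.loglik_index(0.3 * N, N, sigma)
        # perturb one observation away from proportionality
        worse = inf.loglik_index(0.3 * N * np.array([1.5, 1.0]), N, sigma)
        assert worse < base

    def test_beta_continuity_at_zero(self):
        rng = np.random.default_rng(5)
        N = rng.uniform(500, 5000, 4)
        A = rng.uniform(100, 2000, 4)
        sigma = random_psd(4, rng)
        ll0 = inf.loglik_index(A, N, sigma, beta=0.0)
        lleps = inf.loglik_index(A, N, sigma, beta=1e-9)
        assert lleps == pytest.approx(ll0, abs=1e-5)

    def test_tau2_adds_diagonal(self):
        N = np.array([1000.0, 2000.0])
        A = np.array([250.0, 700.0])
        sigma = 0.01 * np.eye(2)
        # adding variance flattens the likelihood of a misfit
        assert inf.loglik_index(A, N, sigma, tau2=0.5) != inf.loglik_index(A, N, sigma)

    def test_vectorized_matches_scalar(self):
        rng = np.random.default_rng(11)
        ny, nd = 6, 50
        sigma = random_psd(ny, rng)
        A = rng.uniform(100, 1000, ny)
        Nmat = rng.uniform(500, 8000, (nd, ny))
        beta = rng.uniform(-0.1, 0.1, nd)
        tau2 = rng.uniform(0, 0.05, nd)
        ll_vec, logq_vec = inf._index_loglik_vectorized(
            np.log(A), np.log(Nmat), sigma, beta, tau2
        )
        for i in range(nd):
            expect = inf.loglik_index(A, Nmat[i], sigma, beta[i], tau2[i])
            assert ll_vec[i] == pytest.approx(expect, rel=1e-9)
            qh = inf.analytic_q(A, Nmat[i], sigma + tau2[i] * np.eye(ny), beta[i])
            assert np.exp(logq_vec[i]) == pytest.approx(qh, rel=1e-9)


class TestLoglikAbsolute:
    def test_maximum_at_estimate(self):
        peak = inf.loglik_absolute(4245.0)
        assert peak > inf.loglik_absolute(4245.0 * 1.01)
        assert peak > inf.loglik_absolute(4245.0 / 1.01)

    def test_variance_value(self):
        # log(1 + (245/4245)^2) from the printed estimate and SE
        assert inf.absolute_obs_variance() == pytest.approx(3.3253e-3, rel=1e-3)

    def test_log_scale_symmetry(self):
        for c in (1.3, 2.0, 5.0):
            assert inf.loglik_absolute(4245.0 * c) == pytest.approx(
                inf.loglik_absolute(4245.0 / c)
            )

    def test_positive_abundance_required(self):
        with pytest.raises(ValueError):
            inf.loglik_absolute(0.0)


class TestImportanceResample:
    def test_constant_likelihood_returns_prior(self):
        rng = np.random.default_rng(0)
        lw = np.zeros(50_000)
        idx = inf.importance_resample(lw, 50_000, rng)
        # resampled uniform indices: mean near the middle
        assert np.mean(idx) == pytest.approx(25_000, rel=0.02)

    def test_shift_invariance(self):
        lw = np.array([0.0, -1.0, -2.0, -np.inf])
        a = inf.importance_resample(lw, 1000, np.random.default_rng(3))
        b = inf.importance_resample(lw + 123.4, 1000, np.random.default_rng(3))
        assert np.array_equal(a, b)

    def test_zero_weight_never_chosen(self):
        lw = np.array([0.0, -np.inf])
        idx = inf.importance_resample(lw, 500, np.random.default_rng(1))
        assert (idx == 0).all()

    def test_all_zero_weights_fail(self):
        with pytest.raises(RuntimeError, match="all importance weights"):
            inf.importance_resample(np.full(5, -np.inf), 10, np.random.default_rng(0))

    def test_conjugate_toy_posterior(self):
        """SIR on uniform prior + binomial(10, p) likelihood with 7
        successes must reproduce Beta(8, 4) moments."""
        rng = np.random.default_rng(2024)
        p = rng.uniform(0, 1, 200_000)
        loglik = 7 * np.log(p) + 3 * np.log1p(-p)
        idx = inf.importance_resample(loglik, 20_000, rng)
        post = p[idx]
        assert post.mean() == pytest.approx(beta_dist(8, 4).mean(), abs=0.005)
        assert post.std() == pytest.approx(beta_dist(8, 4).std(), abs=0.005)
        q = np.percentile(post, [10, 50, 90])
        expect = beta_dist(8, 4).ppf([0.1, 0.5, 0.9])
        assert np.allclose(q, expect, atol=0.01)


class TestRunSir:
    def test_smoke_and_diagnostics(self, small_bundle):
        ds, bundle = small_bundle
        post = inf.run_sir(
            inf.base_priors(), bundle, n_importance=4000, n_out=2000, seed=5
        )
        assert len(post.draws) == 2000
        assert 0 < post.n_unique <= 2000
        assert 0 < post.feasible_fraction <= 1
        assert np.isfinite(post.log_marginal)
        assert (post.draws["k"] > 0).all()
        assert (post.draws["q_hat"] > 0).all()
        # truth within the 95% interval for K on this single dataset
        lo, hi = np.percentile(post.draws["k"], [2.5, 97.5])
        assert lo <= ds.truth.k <= hi

    def test_unique_count_decreases_with_concentration(self, small_bundle):
        _, bundle = small_bundle
        rng = np.random.default_rng(0)
        lw_flat = np.zeros(5000)
        lw_peaked = np.where(np.arange(5000) == 17, 0.0, -50.0)
        u_flat = np.unique(inf.importance_resample(lw_flat, 2000, rng)).size
        u_peak = np.unique(inf.importance_resample(lw_peaked, 2000, rng)).size
        assert u_peak < u_flat

    def test_seed_reproducible(self, small_bundle):
        _, bundle = small_bundle
        a = inf.run_sir(inf.base_priors(), bundle, n_importance=2000, n_out=500, seed=9)
        b = inf.run_sir(inf.base_priors(), bundle, n_importance=2000, n_out=500, seed=9)
        pd.testing.assert_frame_equal(a.draws, b.draws)
        assert a.log_marginal == b.log_marginal


class TestPosteriorQDraws:
    def test_q_draws_positive(self, small_bundle):
        _, bundle = small_bundle
        post = inf.run_sir(
            inf.base_priors(), bundle, n_importance=1500, n_out=300, seed=2
        )
        qs = inf.posterior_q_draws(post, bundle.index_a, bundle.index_sigma, seed=0)
        assert (qs > 0).all()

    def test_median_close_to_qhat_median(self, small_bundle):
        _, bundle = small_bundle
        post = inf.run_sir(
            inf.base_priors(), bundle, n_importance=1500, n_out=1000, seed=3
        )
        qs = inf.posterior_q_draws(post, bundle.index_a, bundle.index_sigma, seed=1)
        assert np.median(qs) == pytest.approx(post.draws["q_hat"].median(), rel=0.05)

    def test_degenerate_sigma_limit(self, small_bundle):
        _, bundle = small_bundle
        post = inf.run_sir(
            inf.base_priors(), bundle, n_importance=1500, n_out=200, seed=4
        )
        # a huge 1' Sigma^-1 1 (near-zero variance) pins q at q_hat
        sigma = np.eye(len(bundle.index_years)) * 1e-14
        qs = inf.posterior_q_draws(post, bundle.index_a, sigma, seed=2)
        assert np.allclose(qs, post.draws["q_hat"], rtol=1e-3)


class TestPostModelPreData:
    def test_zero_catches_returns_prior(self):
        bounds = pd.DataFrame({"year": [1700], "c_min": [0.0], "c_max": [0.0]})
        out = inf.post_model_pre_data(
            inf.base_priors(), bounds, n_draws=20_000, seed=0
        )
        assert out.feasible_fraction == 1.0
        # marginals match the prior (KS-style quantile check)
        for col, (lo, hi) in [("r_max", (0, 0.11)), ("p_msy", (0.5, 0.8))]:
            x = out.draws[col]
            grid = np.percentile(x, [25, 50, 75])
            expect = lo + np.array([0.25, 0.5, 0.75]) * (hi - lo)
            assert np.allclose(grid, expect, atol=0.02 * (hi - lo))

    def test_heavy_catches_shift_k_up(self, small_bundle):
        ds, _ = small_bundle
        light = pd.DataFrame({"year": [1700], "c_min": [0.0], "c_max": [0.0]})
        a = inf.post_model_pre_data(inf.base_priors(), light, n_draws=4000, seed=1)
        b = inf.post_model_pre_data(inf.base_priors(), ds.catch_bounds, n_draws=4000, seed=1)
        assert b.draws["k"].median() > a.draws["k"].median()

    def test_feasible_fraction_in_unit_interval(self, small_bundle):
        ds, _ = small_bundle
        out = inf.post_model_pre_data(inf.base_priors(), ds.catch_bounds, n_draws=2000, seed=2)
        assert 0.0 <= out.feasible_fraction <= 1.0
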