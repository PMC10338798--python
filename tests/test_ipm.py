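"""Joint posterior: density components, imputation, sampling, correlation."""

import numpy as np
import pytest
from dataclasses import replace
from scipy import stats
from scipy.special import expit

from _oracles import individual_cjs_loglik, multinomial_constant

from seabird_ipm import (
    ColonyDataset,
    Formulation,
    MCMCSettings,
    PosteriorSamples,
    RunConfig,
    build_posterior,
    derive_correlation,
    impute_initial_counts,
    sample_posterior,
    scenario,
    simulate_colony_dataset,
)
from seabird_ipm.ipm import PosteriorSpec
from seabird_ipm.marray import cell_probabilities, TrapClass


class TestImputeInitialCounts:
    def test_two_point_mean_and_sd(self):
        """Missing anchor years draw from Normal(mean, SD) of the two
        nearest censuses: for 100 and 120 that is Normal(110, 14.14)."""
        counts = np.array([np.nan, np.nan, 100.0, np.nan, 120.0, np.nan])
        draws = np.array(
            [impute_initial_counts(counts, 2, seed=s)[0] for s in range(4000)]
        )
        assert draws.mean() == pytest.approx(110.0, abs=1.0)
        assert draws.std(ddof=1) == pytest.approx(np.sqrt(200), abs=0.7)

    def test_observed_years_pass_through(self):
        counts = np.array([90.0, 95.0, 100.0, np.nan, 120.0])
        anchors = impute_initial_counts(counts, 3, seed=0)
        np.testing.assert_array_equal(anchors, [90.0, 95.0, 100.0])

    def test_requires_two_censuses(self):
        with pytest.raises(ValueError, match="2 censuses"):
            impute_initial_counts(np.array([np.nan, 50.0, np.nan]), 2, seed=0)

    def test_sparse_schedule_coverage(self):
        """A census pattern with 8 of 36 years observed still yields a
        finite anchor for every initialisation year."""
        counts = np.full(36, np.nan)
        observed_years = np.array([0, 5, 8, 14, 19, 24, 29, 33])
        counts[observed_years] = 10_000 + 500 * np.sin(observed_years)
        anchors = impute_initial_counts(counts, 5, seed=1)
        assert np.isfinite(anchors).all() and (anchors > 0).all()


def micro_dataset() -> ColonyDataset:
    years = np.arange(2000, 2004)
    return ColonyDataset(
        colony_id="micro",
        years=years,
        histories=np.array([[1, 1, 0, 1], [1, 0, 1, 0]]),
        pairs_monitored=np.array([2, 2, 2, 2]),
        chicks_fledged=np.array([1, 2, 0, 1]),
        counts=np.array([20.0, 22.0, np.nan, 21.0]),
    )


def micro_point(spec: PosteriorSpec) -> dict:
    T, d = spec.T, spec.config.d
    return {
        "mu_phi": 1.5, "mu_f": 0.2, "mu_p": 0.3, "alpha": 0.8,
        "phi_im": 0.5, "sigma_p": 0.4, "sigma_y": 3.0,
        "delta1": 0.3, "delta2": 0.4, "lam": 0.2,
        "eta1": np.linspace(-0.5, 0.5, T - 1),
        "eta2": np.linspace(0.3, -0.3, T),
        "eta_p": np.full(T, 0.1),
        "n0": spec.anchors * 1.02,
        "N": np.array([20, 21, 21, 22]),
        "R": np.array([-1, -1, 1, 2]),
        "S": np.array([-1, -1, 20, 20]),
    }


class TestLogDensity:
    @pytest.fixture()
    def micro_spec(self):
        config = RunConfig(d=2, mcmc=MCMCSettings(seed=5))
        return build_posterior(micro_dataset(), config)

    def test_finite_at_admissible_point(self, micro_spec):
        total = micro_spec.log_density(micro_point(micro_spec))
        assert np.isfinite(total)

    def test_components_sum_to_total(self, micro_spec):
        point = micro_point(micro_spec)
        comps = micro_spec.log_density_components(point)
        assert set(comps) == {
            "cjs", "productivity", "state_space", "random_effects", "priors"
        }
        assert sum(comps.values()) == pytest.approx(
            micro_spec.log_density(point), abs=1e-10
        )

    def test_hand_assembled_density(self, micro_spec):
        """Every block re-derived independently with scipy primitives."""
        point = micro_point(micro_spec)
        comps = micro_spec.log_density_components(point)
        phi, f, p = micro_spec.rates(point)

        # CJS block: brute-force individual likelihood plus the
        # parameter-free multinomial coefficients of this m-array.
        h = micro_dataset().histories
        expected_cjs = individual_cjs_loglik(
            h, phi, p, point["alpha"]
        ) + multinomial_constant(micro_spec.marr)
        assert comps["cjs"] == pytest.approx(expected_cjs, abs=1e-10)

        expected_prod = sum(
            stats.binom.logpmf(j, e, f[t])
            for t, (e, j) in enumerate(zip([2, 2, 2, 2], [1, 2, 0, 1]))
        )
        assert comps["productivity"] == pytest.approx(expected_prod, abs=1e-10)

        N, R, S = point["N"], point["R"], point["S"]
        n0 = point["n0"]
        anchors, sd0 = micro_spec.anchors, 0.2 * micro_spec.anchors
        expected_state = sum(
            stats.norm.logpdf(n0[t], anchors[t], sd0[t])
            - np.log(stats.norm.sf(0, anchors[t], sd0[t]))
            + stats.poisson.logpmf(N[t], n0[t])
            for t in range(2)
        )
        for t in (2, 3):
            rec = f[t - 2] * point["phi_im"] * phi[t - 1] * 0.5
            expected_state += stats.binom.logpmf(R[t], N[t - 2], rec)
            expected_state += stats.binom.logpmf(S[t], N[t - 1], phi[t - 1])
        for t, c in [(0, 20.0), (1, 22.0), (3, 21.0)]:
            expected_state += stats.norm.logpdf(c, N[t], point["sigma_y"])
        assert comps["state_space"] == pytest.approx(expected_state, abs=1e-10)

        expected_ran = (
            stats.norm.logpdf(point["eta1"]).sum()
            + stats.norm.logpdf(point["eta2"]).sum()
            + stats.norm.logpdf(point["eta_p"]).sum()
        )
        assert comps["random_effects"] == pytest.approx(expected_ran, abs=1e-10)

    def test_inconsistent_latents_have_zero_support(self, micro_spec):
        point = micro_point(micro_spec)
        point["N"] = np.array([20, 21, 25, 22])  # breaks N = R + S
        assert micro_spec.log_density(point) == -np.inf

    def test_year_count_guard(self):
        with pytest.raises(ValueError, match="years"):
            build_posterior(micro_dataset(), RunConfig(d=3))


class TestFittedPosterior:
    def test_sampler_converges_on_synthetic_data(self, fitted_small):
        _, samples, _ = fitted_small
        finite = [
            float(np.nanmax(np.atleast_1d(v))) for v in samples.rhat.values()
        ]
        assert samples.converged
        assert max(v for v in finite if np.isfinite(v)) <= 1.1

    def test_latent_accounting_in_every_draw(self, fitted_small):
        _, samples, _ = fitted_small
        N = samples.stacked("N")
        R = samples.stacked("R")
        S = samples.stacked("S")
        d = samples.d
        np.testing.assert_allclose(N[:, d:], R[:, d:] + S[:, d:], atol=1e-9)
        assert np.isnan(R[:, :d]).all()  # recruits undefined in anchor years

    def test_posterior_means_near_truth(self, fitted_small):
        """Point recovery on a short series: generous sanity bands."""
        _, samples, truth = fitted_small
        surv = samples.stacked("phi").mean()
        prod = samples.stacked("f").mean()
        assert surv == pytest.approx(truth.params.mean_survival, abs=0.05)
        assert prod == pytest.approx(truth.params.mean_productivity, abs=0.07)

    def test_posterior_predictive_row_sums(self, fitted_small):
        """Re-simulated m-array rows keep the observed release totals."""
        spec, samples, _ = fitted_small
        rng = np.random.default_rng(0)
        phi = samples.stacked("phi")[0]
        p = samples.stacked("p")[0]
        alpha = samples.stacked("alpha")[0]
        combined = spec.marr.combined()
        for i in range(spec.T - 1):
            n_rel = combined[i].sum()
            if n_rel == 0:
                continue
            pr = cell_probabilities(phi, p, alpha, TrapClass.SEEN_PREV, i)
            sim = rng.multinomial(n_rel, pr)
            assert sim.sum() == n_rel


class TestFormulationSymmetry:
    def test_lag_swap_leaves_marginals_unchanged_without_correlation(self):
        """On data generated with zero lag-specific correlation, fitting
        the PRE versus the POST pairing shifts the marginal survival and
        productivity posteriors by a negligible amount."""
        params = replace(scenario("IOM_LIKE", "pre"), rho=0.0)
        mon = ["mu_phi", "mu_f"]
        diffs_surv, diffs_prod = [], []
        for seed in (201, 202, 203):
            dataset, _ = simulate_colony_dataset(
                params, T=14, n_new_marked_per_year=30, pairs_monitored=80,
                seed=seed,
            )
            means = {}
            for form in (Formulation.PRE, Formulation.POST):
                config = RunConfig(
                    formulation=form,
                    mcmc=MCMCSettings(n_iter=2500, n_burn=800, thin=2),
                )
                spec = build_posterior(dataset, config)
                s = sample_posterior(
                    spec, seed=seed, monitors=mon, compute_rhat=False
                )
                means[form] = (
                    expit(s.stacked("mu_phi")).mean(),
                    expit(s.stacked("mu_f")).mean(),
                )
            diffs_surv.append(means[Formulation.PRE][0] - means[Formulation.POST][0])
            diffs_prod.append(means[Formulation.PRE][1] - means[Formulation.POST][1])
        assert abs(np.mean(diffs_surv)) < 0.02
        assert abs(np.mean(diffs_prod)) < 0.02


class TestDeterminism:
    def test_same_seed_same_draws(self, small_dataset):
        dataset, _ = small_dataset
        config = RunConfig(mcmc=MCMCSettings(n_iter=400, n_burn=100, thin=1))
        spec = build_posterior(dataset, config)
        mon = ["mu_phi", "r", "N"]
        a = sample_posterior(spec, seed=3, monitors=mon, compute_rhat=False)
        b = sample_posterior(spec, seed=3, monitors=mon, compute_rhat=False)
        for name in mon:
            np.testing.assert_array_equal(a.posterior[name], b.posterior[name])


class TestPriorRecovery:
    def test_prior_only_matches_prior(self, small_dataset):
        """With every likelihood block off, the marginal of mu_phi is its
        Normal(0, 10) prior."""
        dataset, _ = small_dataset
        config = RunConfig(mcmc=MCMCSettings(n_iter=6000, n_burn=1000, thin=1))
        spec = build_posterior(dataset, config)
        samples = sample_posterior(
            spec, seed=11, monitors=["mu_phi"], prior_only=True,
            compute_rhat=False,
        )
        draws = samples.stacked("mu_phi")
        assert draws.mean() == pytest.approx(0.0, abs=0.6)
        assert draws.std() == pytest.approx(10.0, rel=0.06)
        assert np.quantile(draws, 0.25) == pytest.approx(
            stats.norm.ppf(0.25, 0, 10), abs=1.0
        )


def _fake_sigma_samples(sig_phi, sig_f, cov):
    n = sig_phi.shape[0]
    post = {
        "sig_phi": sig_phi[None, :],
        "sig_f": sig_f[None, :],
        "cov_pf": cov[None, :],
    }
    return PosteriorSamples(
        posterior=post,
        years=np.arange(2000, 2010),
        formulation=Formulation.PRE,
        d=5,
        provenance={},
    )


class TestDeriveCorrelation:
    def test_diagonal_covariance_gives_zero(self):
        s = np.full(50, 0.3)
        samples = _fake_sigma_samples(s, np.full(50, 0.5), np.zeros(50))
        corr = derive_correlation(samples)
        assert corr.mean == 0.0 and corr.prob_positive == 0.0

    def test_perfect_correlation(self):
        s = np.full(50, 0.4)
        samples = _fake_sigma_samples(s, s, s**2)
        corr = derive_correlation(samples)
        np.testing.assert_allclose(corr.draws, 1.0, atol=1e-12)

    def test_strict_paper_wording_mode(self):
        """cov / (var + var) for audit: 0.5 for a perfectly correlated
        equal-variance pair, and not bounded by construction."""
        s = np.full(50, 0.4)
        samples = _fake_sigma_samples(s, s, s**2)
        corr = derive_correlation(samples, strict_paper_wording=True)
        np.testing.assert_allclose(corr.draws, 0.5, atol=1e-12)

    def test_zero_variance_flagged(self):
        samples = _fake_sigma_samples(
            np.zeros(10), np.full(10, 0.5), np.zeros(10)
        )
        corr = derive_correlation(samples)
        assert corr.n_zero_variance == 10
        assert corr.mean == 0.0
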