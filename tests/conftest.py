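import numpy as np
import pytest

from seabird_ipm import (
    DemographicParams,
    Formulation,
    MCMCSettings,
    PosteriorSamples,
    RunConfig,
    build_posterior,
    sample_posterior,
    scenario,
    simulate_colony_dataset,
)


@pytest.fixture(scope="session")
def iom_params() -> DemographicParams:
    return scenario("IOM_LIKE")


@pytest.fixture(scope="session")
def small_dataset(iom_params):
    """A small but complete synthetic colony (14 years, 40 marks/year)."""
    dataset, truth = simulate_colony_dataset(
        iom_params,
        T=14,
        n_new_marked_per_year=40,
        pairs_monitored=80,
        seed=101,
    )
    return dataset, truth


@pytest.fixture(scope="session")
def fitted_small(small_dataset):
    """One shared short JAGS fit of the small colony, reused across tests."""
    dataset, truth = small_dataset
    config = RunConfig(mcmc=MCMCSettings(n_iter=3000, n_burn=1000, thin=2))
    spec = build_posterior(dataset, config)
    samples = sample_posterior(spec, seed=7)
    return spec, samples, truth


@pytest.fixture()
def fake_posterior() -> PosteriorSamples:
    """A hand-built posterior with known draws (no sampler involved)."""
    rng = np.random.default_rng(42)
    n_chain, n_draw, T, d = 2, 200, 12, 5
    N = np.empty((n_chain, n_draw, T))
    N[..., 0] = 500.0
    growth = 1.0 + rng.normal(0.01, 0.02, size=(n_chain, n_draw, T - 1))
    for t in range(1, T):
        N[..., t] = N[..., t - 1] * growth[..., t - 1]
    sig_phi = np.full((n_chain, n_draw), 0.3)
    sig_f = np.full((n_chain, n_draw), 0.5)
    posterior = {
        "mu_phi": rng.normal(2.4, 0.1, (n_chain, n_draw)),
        "mu_f": rng.normal(0.9, 0.1, (n_chain, n_draw)),
        "alpha": rng.normal(2.3, 0.1, (n_chain, n_draw)),
        "phi_im": rng.uniform(0.45, 0.55, (n_chain, n_draw)),
        "sig_phi": sig_phi,
        "sig_f": sig_f,
        "cov_pf": 0.5 * sig_phi * sig_f,
        "phi": np.clip(rng.normal(0.92, 0.01, (n_chain, n_draw, T - 1)), 0, 1),
        "f": np.clip(rng.normal(0.71, 0.02, (n_chain, n_draw, T)), 0, 1),
        "p": np.clip(rng.normal(0.7, 0.02, (n_chain, n_draw, T)), 0, 1),
        "N": N,
    }
    return PosteriorSamples(
        posterior=posterior,
        years=np.arange(1990, 1990 + T),
        formulation=Formulation.PRE,
        d=d,
        provenance={"colony_id": "fake"},
        rhat={},
        converged=True,
    )
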