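# seabird-ipm

Integrated population models (IPMs) for colonies of long-lived seabirds,
with **cross-season correlated annual random effects** on adult survival
and productivity, and a **transient life-table response experiment
(LTRE)** that decomposes the variance of realised population growth.

The package is for population ecologists who have, for one colony, the
three classic annual data streams —

* capture–mark–resight histories of breeding adults,
* productivity trials (monitored pairs `E_t`, fledged chicks `J_t`),
* breeding-pair counts `C_t`, possibly with missing years —

and want to estimate demographic rates, their *temporal correlation
across seasons*, and what each rate (and the correlation) contributes to
fluctuations in population growth.  A full synthetic-data generator with
known ground truth makes every stage testable without any field data.

## The model

Survival, resighting and productivity vary annually on the logit scale:

    logit(phi_t) = mu_phi + eps_phi_t        (CJS m-array, trap effect alpha)
    logit(p_t)   = mu_p   + eps_p_t
    logit(F_t)   = mu_f   + eps_f_t          (J_t ~ Bin(E_t, F_t))

with a one-year trap-dependence: birds sighted at t − 1 are resighted at
t with rate `logit⁻¹(logit(p_t) + alpha)`.  Counts follow a state-space
model for breeding females with recruitment at age d (default 5):

    R_t ~ Bin(N_{t−d}, F_{t−d} · phi_im · phi_{t−1→t} · 0.5)
    S_t ~ Bin(N_{t−1}, phi_{t−1→t}),   N_t = R_t + S_t
    y_t ~ Normal(b · N_t, sigma_y²)

The survival and productivity deviations `(eps_phi, eps_f)` are bivariate
normal with correlation `r`, at either of two lags:

* **pre** — survival over t − 1 → t with productivity in year t
  (winter conditions carry over into breeding), or
* **post** — productivity in year t with survival over t → t + 1
  (breeding conditions carry over into the next winter).

The covariance is parameterised by a Cholesky factorisation with
parameter expansion (normal priors on the loading and scales).  Sampling
is by MCMC with JAGS (discrete latent states, bit-reproducible under a
seed); the same joint density is exposed in Python block by block for
verification.  The transient-LTRE then writes

    var(lambda_t) ≈ Σ_ij cov(theta_i, theta_j) · (dλ/dθ_i)(dλ/dθ_j),
    theta_t = (phi_t, F'_t, q_t),  q_t = N_{t+1−d}/N_t,

with analytic sensitivities at mean rates, giving variance contributions
(diagonal) and covariance contributions (off-diagonal, doubled), raw and
as shares of the total.

See `docs/methods.md` for priors, numerical choices and limitations.

## Worked example

```python
from seabird_ipm import *
from seabird_ipm.ltre import ltre_from_posterior

params = scenario("IOM_LIKE", "pre")        # stable colony preset, rho = 0.51
dataset, truth = simulate_colony_dataset(
    params, T=20, n_new_marked_per_year=50, pairs_monitored=100, seed=42
)
config = RunConfig(mcmc=MCMCSettings(n_iter=6000, n_burn=1500, thin=3, seed=42))
samples = sample_posterior(build_posterior(dataset, config), seed=42)
corr = derive_correlation(samples)
report = summary_report(samples, ltre_from_posterior(samples, seed=0), corr)
```

The rounded report for this seed prints:

    converged: True
    adult_survival              {'mean': 0.92, 'ci_low': 0.91, 'ci_high': 0.93}
    productivity                {'mean': 0.69, 'ci_low': 0.67, 'ci_high': 0.71}
    immature_survival_compound  {'mean': 0.44, 'ci_low': 0.39, 'ci_high': 0.49}
    immature_survival_annual    {'mean': 0.82, 'ci_low': 0.79, 'ci_high': 0.84}
    trap_dependence_alpha       {'mean': 2.19, 'ci_low': 1.85, 'ci_high': 2.51}
    geometric_mean_lambda       {'mean': 1.03, 'ci_low': 1.03, 'ci_high': 1.04}
    trend_slope                 {'mean': 0.0,  'ci_low': -0.0, 'ci_high': 0.0}
    correlation_r               {'mean': 0.9, 'ci_low': 0.57, 'ci_high': 1.0,
                                 'prob_positive': 1.0}

Survival (0.92), productivity (0.69 vs 0.71 generated), the
trap-dependence offset (2.19 vs 2.34) and immature survival (0.44 vs
0.49) are recovered within their intervals; the colony grows ~3%/year
with no trend.  The correlation posterior is positive but wide — with
only 19 paired year-effects, single-replicate correlation estimates are
imprecise (this draw's mean, 0.90, overshoots the generating 0.51; the
test suite shows the estimator is centred once averaged over replicate
datasets).  The LTRE table for the same fit attributes ~42% of
var(lambda_t) to survival variance, ~10% to productivity variance and
~38% to their covariance.

The same pipeline is scriptable from the shell:

    seabird-ipm simulate --scenario ROST_LIKE --years 30 --seed 1 --out colony/
    seabird-ipm fit --colony-dir colony/ --formulation pre --seed 1 --out fit/
    seabird-ipm ltre --posterior fit/posterior.npz --out ltre/
    seabird-ipm report --posterior fit/posterior.npz --out report/

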