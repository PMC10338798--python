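# Methods

## The model

`seabird_ipm` fits an integrated population model (IPM) for a single
colony of a long-lived seabird with delayed recruitment (the default age
at first breeding is d = 5, as for Atlantic puffins).  Three annual data
streams are analysed jointly, sharing parameters through one posterior:

**Capture–mark–resight.**  Adult histories are reduced to m-arrays and
modelled with a Cormack–Jolly–Seber likelihood conditioned on first
capture.  Annual apparent survival and resighting are modelled on the
logit scale, `logit(phi_t) = mu_phi + eps_phi_t` and
`logit(p_t) = mu_p + eps_p_t`, with a one-year trap-dependence structure:
a bird sighted at occasion t − 1 is resighted at t with the elevated rate
`logit⁻¹(logit(p_t) + alpha)`, with constant `alpha`.  Because every
m-array release is itself a sighting, the occasion immediately after a
release always carries the trap-aware rate; later occasions in the row use
the baseline rate.  The m-array is additionally stratified into releases
that were or were not sighted at the occasion *preceding* release (the
marking occasion counts as seen).  Under the constant one-year trap effect
this stratification is likelihood-neutral — both classes were in hand at
release — and it is kept as the sufficient stratification for more general
trap-response structures and for audit.  The sampler consumes the
class-summed m-array, which has an identical likelihood up to multinomial
constants.  Equality of the m-array likelihood with a brute-force
individual-level likelihood (enumerating latent death occasions) is
enforced by test to 1e−8 up to that parameter-free constant.

**Productivity.**  Annual trials `J_t ~ Binomial(E_t, F_t)` with
`logit(F_t) = mu_f + eps_f_t`, where `E_t` monitored pairs fledge `J_t`
chicks.

**Counts.**  A state-space model for breeding females.  The first d years
are anchor years whose sizes have priors centred on observed (or imputed)
counts; from year d + 1,

    R_t ~ Binomial(N_{t−d}, F_{t−d} · phi_im · phi_{t−1→t} · 0.5)
    S_t ~ Binomial(N_{t−1}, phi_{t−1→t})
    N_t = R_t + S_t
    y_t ~ Normal(b · N_t, sigma_y²)        (observed census years only)

`phi_im` compounds immature survival from fledging to the year before
recruitment with natal philopatry and net movement; the 0.5 is the
fledgling sex ratio; survival over the winter before recruitment is the
adult rate.  Breeding propensity `b` defaults to 1; setting `b = 0.9`
reproduces a propensity sensitivity without touching any other code path.
Missing census years contribute no observation term.  Anchor years whose
counts are missing are imputed as draws from a normal with the mean and SD
(one degree of freedom) of the two nearest censuses; imputations are
anchors and initial values, never data.

**Cross-season correlation.**  The annual deviations of survival and
productivity are bivariate normal at one of two lags:

* `pre`: survival over t − 1 → t pairs with productivity in year t
  (non-breeding-season conditions carrying over into breeding);
* `post`: productivity in year t pairs with survival over t → t + 1
  (breeding-season conditions carrying over into the next winter).

The two formulations differ *only* in the index shift used when pairing
`(eps_phi, eps_f)`; every other code path is shared.  The year left
unpaired by the lag receives an independent deviation with the marginal
productivity SD.  The covariance matrix uses a Cholesky factorisation with
parameter expansion: `eps_phi = delta1 · z1` and
`eps_f = lam · z1 + delta2 · z2` with standard-normal latents, positive
scales `delta1, delta2` and an unconstrained loading `lam` under normal
priors.  This implies `sigma_phi = delta1`,
`sigma_f = sqrt(lam² + delta2²)`, `cov = lam · delta1`, and the derived
correlation `r = cov / (sigma_phi · sigma_f)`, which is guaranteed to lie
in [−1, 1].  An alternative scaled covariance, `cov / (sigma_phi² +
sigma_f²)`, is available for audit via
`derive_correlation(..., strict_paper_wording=True)`; it is not a
correlation coefficient and is reported only on request.  `Pr(r > 0)` is
the fraction of posterior draws above zero; draws with a zero-variance
denominator are set to 0 and counted.

## Priors

| parameter | prior | rationale |
|---|---|---|
| `mu_phi, mu_f, mu_p, alpha` | Normal(0, 10²) on logit | weakly informative |
| `phi_im` | Uniform(0, 1) | compound probability, no prior information |
| `delta1, delta2` | Half-Normal(0, 2²) | scales of annual deviations |
| `lam` | Normal(0, 2²) | covariance loading |
| `sigma_p` | Uniform(0, 3) | resighting deviation SD (logit) |
| `sigma_y` | Uniform(0, 10 · max count) | census error SD (count units) |
| anchor `n0_t` | Normal(anchor_t, (0.2 · anchor_t)²) T(0,) | ±20% spread around the anchor count |
| `N_t`, t ≤ d | Poisson(n0_t) | integer initial sizes with the anchor spread |

The Poisson layer exists because initial population sizes enter binomial
sizes and must be integers; its extra variance is negligible relative to
the 20% anchor spread at realistic colony sizes.

## Sampling

The joint density is authored twice from one specification: a Python
log-density with retrievable named blocks (`cjs`, `productivity`,
`state_space`, `random_effects`, `priors`) used for verification, and a
generated JAGS model used for sampling (rjags driven through Rscript;
latent states are discrete and sampled directly — no continuous
relaxation; the choice is recorded in the provenance of every result).
Per-chain RNG seeds make runs bit-reproducible.  Library defaults are 3
chains × 20,000 iterations (5,000 burn-in, thin 2);
`MCMCSettings.paper_scale()` gives 3 × 500,000 / 50,000 / thin 10 for
publication-scale runs.  Convergence is summarised by rank-normalised
split R-hat per monitored quantity; any value above 1.1 flags the result
as non-converged (a flag, never an exception).

## Transient-LTRE

Realised growth is `lambda_t = N_{t+1} / N_t` from the latent draws.  To
first order `lambda_t = phi_t (1 + 0.5 · phi_im · F'_t · q_t)` with
structure ratio `q_t = N_{t+1−d} / N_t`.  Per posterior draw, the temporal
covariance matrix of `theta_t = (phi_t, F'_t, q_t)` is weighted by the
outer product of the analytic sensitivities evaluated at the draw's mean
rates,

    d lambda / d phi = 1 + 0.5 · phi_im · F̄ · q̄
    d lambda / d F   = 0.5 · phī · phi_im · q̄
    d lambda / d q   = 0.5 · phī · phi_im · F̄,

giving variance contributions on the diagonal and doubled covariance
contributions off it; they sum exactly to the first-order approximation of
var(lambda_t).  `F'_t` follows the lag of the fitted formulation when
paired with `phi_t` (pre: F of the interval's end year; post: of its start
year), so the covariance term reflects the correlation the model actually
estimated.  Scaled contributions divide by the first-order total and sum
to one; because the population-structure ratio is an inference about what
"population structures" comprise, a demographic-only scaling over the
three demographic terms (survival, productivity, their covariance) is also
reported for comparability with decompositions that show only those.  The
ratio of the first-order total to the brute-force empirical var(lambda_t)
is reported as an approximation diagnostic.  The decomposition defaults to
10,000 posterior draws, subsampled with a fixed seed when more are
available.  Constant rate series make every contribution zero; such draws
are flagged degenerate and excluded from scaled summaries.

## The synthetic generator

The generator produces data with exactly the statistical structure the
model assumes: logit-normal annual variation, the bivariate
survival–productivity deviations at either lag, binomial population
dynamics with age-d recruitment, one-year trap-dependent resighting
(marking counts as seen; newly marked birds enter as established breeders
so adult survival applies immediately), binomial productivity trials, and
truncated-normal census error applied after propensity thinning
(`C_t ≈ b · N_t`).  Scenario presets encode three contrasting regimes
whose mean survival (0.92 / 0.91 / 0.89), productivity (0.71 / 0.14 /
0.74), compound immature survival (0.49 / 0.39 / 0.41), trap-dependence
offset (2.34 / 1.65 / 2.15) and lag-specific correlations (pre 0.51 /
0.18 / 0.35; post 0.47 / 0.46 / 0.01) span a stable-increasing, a
declining low-productivity, and a near-stationary high-productivity
colony.  Annual-deviation SDs are preset at 0.3 (survival), 0.5
(productivity) and 0.5 (resighting) on the logit scale — visible but
realistic year effects for a long-lived seabird; the mean resighting rate
(0.7) and census SD (30 pairs) are likewise package presets, all
overridable per field.

What the generator does **not** emulate — and hence what passing recovery
tests cannot speak to — includes individual heterogeneity and senescence
in survival or detection, tag loss, sex differences, breeding-adult
dispersal, age-structured immature survival, environmental covariates,
count truncation at zero matters only near extinction, and over- or
under-dispersion of census error.  Recovery on synthetic data demonstrates
the estimator is consistent under the model's own assumptions, not that
the model is correct for any particular field system.

## Numerical and design choices

* Calendar years index everything user-facing; 0-based indices never leak
  into files or reports.
* Counts of zero are meaningful; missing censuses are empty CSV fields.
* `cell_probabilities` returns vectors that sum to 1 to ~1e−12; the
  never-seen cell is computed by complement.
* Draws with non-positive population in any year are excluded (and
  flagged) from growth-rate summaries.
* Trend slopes are per-draw OLS of lambda_t on calendar year, so credible
  intervals propagate posterior uncertainty; geometric-mean growth is the
  per-draw endpoint ratio `(N_T / N_1)^(1/(T−1))`.
* Annualisation of compound probabilities (`x^(1/n)`) is applied per draw
  so intervals transform monotonically.
* Reports round to 2 decimals for display while machine output keeps full
  double precision.

## Problem sizes in the automated checks

The test suite runs the replicate-recovery experiments at the package's
test scale: 20 modelled years, 50 newly marked birds per year, 100
monitored pairs, 20 replicate datasets per experiment, and 3 chains ×
4,000 iterations (1,500 burn-in, thin 2) per fit — sizes at which a
recovery experiment completes on a laptop while leaving the acceptance
bands unchanged (split R-hat is below 1.02 already at this chain
length).  The acceptance script fits one 30-year colony at 3 ×
10,000 iterations.  Larger runs (the library's 3 × 20,000 default or
`paper_scale()`) sharpen the same posteriors without changing the
structure of any check.

## Known limitations

* Resighting-rate priors make the final-occasion survival/detection
  product only weakly identified, as in any CJS model; the annual random
  effects regularise it.
* `phi_im` absorbs immigration and emigration; it is not a survival
  probability of any real cohort.
* The LTRE structure ratio `q_t` is derived from latent `N` draws and
  inherits their smoothing; with sparse censuses its contribution is
  prior-influenced in the anchor years.
* A single census-error SD per colony is estimated; count streams with
  year-varying effort would need an observation-model extension.
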