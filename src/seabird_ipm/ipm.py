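"""The integrated population model: joint density, sampling, correlation.

The joint posterior combines four named blocks, each retrievable on its
own from :meth:`PosteriorSpec.log_density_components`:

* ``cjs`` — the trap-dependent m-array multinomial likelihood of the
  resighting histories;
* ``productivity`` — annual binomial trials J_t ~ Bin(E_t, F_t);
* ``state_space`` — the female population process (recruitment at age d:
  R_t ~ Bin(N_{t-d}, F_{t-d} * phi_im * phi_{t-1->t} * 0.5); survivors:
  S_t ~ Bin(N_{t-1}, phi_{t-1->t})), anchor-year priors for N_1..N_d, and
  the normal census observation model y_t ~ N(b * N_t, sigma_y^2);
* ``random_effects`` — the annual logit deviations, with the
  survival-productivity pairs at the formulation's lag drawn from a
  bivariate normal built by a Cholesky factorisation with parameter
  expansion (lower-triangular loading ``lam`` and positive scales
  ``delta1``/``delta2`` with normal priors), so that
  sigma_phi = delta1, sigma_f = sqrt(lam^2 + delta2^2) and
  cov = lam * delta1;
* ``priors`` — weakly informative hyperpriors.

Sampling is delegated to JAGS (discrete latent states are sampled
directly, no continuous relaxation); the model string is generated from
the same specification that defines the Python-side density.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logit

from ._jags import run_jags
from .io_formats import ColonyDataset, RunConfig, MCMCSettings
from .marray import MArrayPair, build_marray, marray_loglik
from .synthetic import Formulation

LOG2 = float(np.log(2.0))


def impute_initial_counts(counts, d: int, seed: int = 0) -> np.ndarray:
    """Anchor values for the first ``d`` modelled years.

    Observed counts are used as they stand.  Each missing anchor year
    receives a draw from Normal(mean, SD) of the two nearest non-missing
    census counts (SD with one degree of freedom), mimicking natural
    fluctuation.  The anchors initialise/anchor the latent population
    sizes; they are never treated as data.
    """
    counts = np.asarray(counts, dtype=float)
    observed = np.flatnonzero(~np.isnan(counts))
    if observed.size < 2:
        raise ValueError("need at least 2 censuses to impute initial counts")
    rng = np.random.default_rng(seed)
    anchors = np.empty(d)
    for t in range(d):
        if not np.isnan(counts[t]):
            anchors[t] = counts[t]
            continue
        nearest = observed[np.argsort(np.abs(observed - t), kind="stable")][:2]
        pair = counts[nearest]
        anchors[t] = rng.normal(pair.mean(), pair.std(ddof=1))
    return np.maximum(anchors, 1.0)


@dataclass(frozen=True)
class PosteriorSpec:
    """Data + parameterisation of the joint posterior for one colony."""

    marr: MArrayPair
    pairs_monitored: np.ndarray
    chicks_fledged: np.ndarray
    counts: np.ndarray
    years: np.ndarray
    anchors: np.ndarray
    config: RunConfig
    colony_id: str = "colony"

    @property
    def T(self) -> int:
        return int(self.years.shape[0])

    @property
    def formulation(self) -> Formulation:
        return self.config.formulation

    @property
    def sigma_y_upper(self) -> float:
        observed = self.counts[~np.isnan(self.counts)]
        return float(self.config.priors.sigma_y_upper_factor * observed.max())

    # ---------------------------------------------------------------- python
    def _eps_f(self, lam, delta2, eta1, eta2):
        """Productivity deviations from the expanded Cholesky factors."""
        T = self.T
        sig_f = np.sqrt(lam**2 + delta2**2)
        eps_f = np.empty(T)
        if self.formulation is Formulation.PRE:
            eps_f[1:] = lam * eta1 + delta2 * eta2[1:]
            eps_f[0] = sig_f * eta2[0]
        else:
            eps_f[:-1] = lam * eta1 + delta2 * eta2[:-1]
            eps_f[-1] = sig_f * eta2[-1]
        return eps_f

    def rates(self, point: dict):
        """(phi, f, p) series implied by a parameter point."""
        eps_phi = point["delta1"] * point["eta1"]
        eps_f = self._eps_f(
            point["lam"], point["delta2"], point["eta1"], point["eta2"]
        )
        phi = expit(point["mu_phi"] + eps_phi)
        f = expit(point["mu_f"] + eps_f)
        p = expit(point["mu_p"] + point["sigma_p"] * point["eta_p"])
        return phi, f, p

    def log_density_components(self, point: dict) -> dict[str, float]:
        """Evaluate the named blocks of the joint log-density at a point.

        ``point`` carries the hyperparameters (mu_phi, mu_f, mu_p, alpha,
        phi_im, sigma_p, sigma_y, delta1, delta2, lam), the standardised
        deviations (eta1: T-1, eta2: T, eta_p: T), the anchor means
        (n0: d) and the latent states (N: T integers; R, S defined from
        year d, index-aligned with N).
        """
        cfg = self.config
        pri = cfg.priors
        T, d = self.T, cfg.d
        phi, f, p = self.rates(point)

        cjs = marray_loglik(self.marr, phi, p, point["alpha"])

        keep = self.pairs_monitored > 0
        productivity = float(
            stats.binom.logpmf(
                self.chicks_fledged[keep], self.pairs_monitored[keep], f[keep]
            ).sum()
        )

        N = np.asarray(point["N"], dtype=np.int64)
        R = np.asarray(point["R"], dtype=np.int64)
        S = np.asarray(point["S"], dtype=np.int64)
        n0 = np.asarray(point["n0"], dtype=float)
        sd0 = pri.init_n_cv * self.anchors
        state = float(
            (
                stats.norm.logpdf(n0, self.anchors, sd0)
                - stats.norm.logsf(0.0, self.anchors, sd0)
            ).sum()
        )
        state += float(stats.poisson.logpmf(N[:d], n0).sum())
        rate_rec = f[: T - d] * point["phi_im"] * phi[d - 1 :] * 0.5
        state += float(stats.binom.logpmf(R[d:], N[: T - d], rate_rec).sum())
        state += float(stats.binom.logpmf(S[d:], N[d - 1 : -1], phi[d - 1 :]).sum())
        if not np.array_equal(N[d:], R[d:] + S[d:]):
            state = -np.inf
        obs = ~np.isnan(self.counts)
        state += float(
            stats.norm.logpdf(
                self.counts[obs], cfg.b * N[obs], point["sigma_y"]
            ).sum()
        )

        ran = float(
            stats.norm.logpdf(point["eta1"]).sum()
            + stats.norm.logpdf(point["eta2"]).sum()
            + stats.norm.logpdf(point["eta_p"]).sum()
        )

        priors = float(
            stats.norm.logpdf(
                [point["mu_phi"], point["mu_f"], point["mu_p"], point["alpha"]],
                0.0,
                pri.mean_sd,
            ).sum()
        )
        for delta in (point["delta1"], point["delta2"]):
            priors += (
                stats.norm.logpdf(delta, 0.0, pri.loading_sd) + LOG2
                if delta > 0
                else -np.inf
            )
        priors += float(stats.norm.logpdf(point["lam"], 0.0, pri.loading_sd))
        priors += (
            -np.log(pri.sigma_p_upper)
            if 0 < point["sigma_p"] < pri.sigma_p_upper
            else -np.inf
        )
        priors += (
            -np.log(self.sigma_y_upper)
            if 0 < point["sigma_y"] < self.sigma_y_upper
            else -np.inf
        )
        if not (0 < point["phi_im"] < 1):
            priors = -np.inf

        return {
            "cjs": cjs,
            "productivity": productivity,
            "state_space": state,
            "random_effects": ran,
            "priors": priors,
        }

    def log_density(self, point: dict) -> float:
        return float(sum(self.log_density_components(point).values()))

    # ------------------------------------------------------------------ jags
    def _marray_rows(self):
        """Class-combined m-array rows with releases, for the sampler.

        The two trap classes have identical cell probabilities under the
        constant one-year trap effect, so their multinomial rows are
        merged (the likelihood is unchanged up to multinomial constants).
        """
        combined = self.marr.combined()
        T = self.T
        ro, rows, rel = [], [], []
        for i in range(T - 1):  # releases at the final occasion carry no info
            n_rel = combined[i].sum()
            if n_rel == 0:
                continue
            # JAGS columns: c in 1..T-1 <-> next sighting at occasion c+1
            row = np.concatenate([combined[i, 1:T], [combined[i, T]]])
            ro.append(i + 1)
            rows.append(row)
            rel.append(n_rel)
        return (
            np.array(ro, dtype=np.int64),
            np.array(rows, dtype=np.int64),
            np.array(rel, dtype=np.int64),
        )

    def jags_data(self, prior_only: bool = False) -> dict:
        cfg = self.config
        pri = cfg.priors
        data = {
            "T": self.T,
            "mean_prec": 1.0 / pri.mean_sd**2,
            "load_prec": 1.0 / pri.loading_sd**2,
        }
        if prior_only:
            return data
        ro, rows, rel = self._marray_rows()
        keep = np.flatnonzero(self.pairs_monitored > 0)
        obs = np.flatnonzero(~np.isnan(self.counts))
        data.update(
            {
                "d": cfg.d,
                "b": cfg.b,
                "nrel": len(ro),
                "ro": ro,
                "marr": rows,
                "rel": rel,
                "nE": keep.size,
                "yearE": keep + 1,
                "E": self.pairs_monitored[keep],
                "J": self.chicks_fledged[keep],
                "nC": obs.size,
                "yearC": obs + 1,
                "y": self.counts[obs],
                "anchor": self.anchors,
                "anchor_prec": 1.0 / (pri.init_n_cv * self.anchors) ** 2,
                "sigp_upper": pri.sigma_p_upper,
                "sigy_upper": self.sigma_y_upper,
            }
        )
        return data

    def jags_model(self, prior_only: bool = False) -> str:
        if self.formulation is Formulation.PRE:
            eps_f_lines = (
                "  eps_f[1] <- sig_f * eta2[1]\n"
                "  for (i in 1:(T - 1)) {"
                " eps_f[i + 1] <- lam * eta1[i] + delta2 * eta2[i + 1] }"
            )
        else:
            eps_f_lines = (
                "  eps_f[T] <- sig_f * eta2[T]\n"
                "  for (i in 1:(T - 1)) {"
                " eps_f[i] <- lam * eta1[i] + delta2 * eta2[i] }"
            )
        header = f"""model {{
  mu_phi ~ dnorm(0, mean_prec)
  mu_f ~ dnorm(0, mean_prec)
  mu_p ~ dnorm(0, mean_prec)
  alpha ~ dnorm(0, mean_prec)
  phi_im ~ dunif(0, 1)
  delta1 ~ dnorm(0, load_prec) T(0,)
  delta2 ~ dnorm(0, load_prec) T(0,)
  lam ~ dnorm(0, load_prec)
  sig_phi <- delta1
  sig_f <- sqrt(lam * lam + delta2 * delta2)
  cov_pf <- lam * delta1
  r <- lam / max(sig_f, 1.0E-12)
  for (i in 1:(T - 1)) {{ eta1[i] ~ dnorm(0, 1) }}
  for (t in 1:T) {{
    eta2[t] ~ dnorm(0, 1)
    eta_p[t] ~ dnorm(0, 1)
  }}
  for (i in 1:(T - 1)) {{ eps_phi[i] <- delta1 * eta1[i] }}
{eps_f_lines}
  for (i in 1:(T - 1)) {{ logit(phi[i]) <- mu_phi + eps_phi[i] }}
  for (t in 1:T) {{
    logit(f[t]) <- mu_f + eps_f[t]
    logit(p[t]) <- mu_p + sigma_p * eta_p[t]
    pstar[t] <- ilogit(mu_p + sigma_p * eta_p[t] + alpha)
  }}
"""
        if prior_only:
            return header + "  sigma_p ~ dunif(0, 3)\n}\n"
        body = """  sigma_p ~ dunif(0, sigp_upper)
  sigma_y ~ dunif(0, sigy_upper)
  tau_y <- pow(sigma_y, -2)

  # productivity trials
  for (k in 1:nE) { J[k] ~ dbin(f[yearE[k]], E[k]) }

  # trap-dependent CJS m-array
  for (k in 1:nrel) {
    pr[k, ro[k]] <- phi[ro[k]] * pstar[ro[k] + 1]
    u[k, ro[k] + 1] <- phi[ro[k]] * (1 - pstar[ro[k] + 1])
    for (j in (ro[k] + 2):(T - 1)) {
      u[k, j] <- u[k, j - 1] * phi[j - 1] * (1 - p[j])
    }
    for (c in (ro[k] + 1):(T - 1)) { pr[k, c] <- u[k, c] * phi[c] * p[c + 1] }
    for (c in 1:(ro[k] - 1)) { pr[k, c] <- 0 }
    pr[k, T] <- 1 - sum(pr[k, 1:(T - 1)])
    marr[k, 1:T] ~ dmulti(pr[k, 1:T], rel[k])
  }

  # female population process and census observation
  for (t in 1:d) {
    n0[t] ~ dnorm(anchor[t], anchor_prec[t]) T(0,)
    N[t] ~ dpois(n0[t])
  }
  for (t in (d + 1):T) {
    rate_rec[t] <- f[t - d] * phi_im * phi[t - 1] * 0.5
    R[t] ~ dbin(rate_rec[t], N[t - d])
    S[t] ~ dbin(phi[t - 1], N[t - 1])
    N[t] <- R[t] + S[t]
  }
  for (k in 1:nC) { y[k] ~ dnorm(b * N[yearC[k]], tau_y) }
}
"""
        return header + body

    def jags_inits(self, n_chains: int, seed: int, prior_only: bool = False):
        """Moderate, slightly overdispersed starting points per chain."""
        T = self.T
        with np.errstate(divide="ignore"):
            crude_f = np.clip(
                self.chicks_fledged.sum() / max(self.pairs_monitored.sum(), 1),
                0.05,
                0.95,
            )
        rng = np.random.default_rng(seed)
        inits = []
        for c in range(n_chains):
            jitter = rng.normal(0.0, 0.1, 6)
            init = {
                "mu_phi": 2.0 + jitter[0],
                "mu_f": float(logit(crude_f)) + jitter[1],
                "mu_p": 0.5 + jitter[2],
                "alpha": 1.0 + jitter[3],
                "phi_im": float(np.clip(0.5 + jitter[4], 0.05, 0.95)),
                "delta1": 0.3,
                "delta2": 0.5,
                "lam": float(jitter[5]),
                "sigma_p": 0.5,
                "eta1": np.zeros(T - 1),
                "eta2": np.zeros(T),
                "eta_p": np.zeros(T),
                ".RNG.name": "base::Mersenne-Twister",
                ".RNG.seed": int(seed + 1000 * c + 1),
            }
            if not prior_only:
                observed = self.counts[~np.isnan(self.counts)]
                init["sigma_y"] = float(max(1.0, 0.05 * observed.max()))
                init["n0"] = self.anchors.copy()
            inits.append(init)
        return inits


def build_posterior(dataset: ColonyDataset, config: RunConfig) -> PosteriorSpec:
    """Assemble the joint posterior specification from a validated dataset."""
    if dataset.n_years <= config.d + 1:
        raise ValueError(
            f"need more than d + 1 = {config.d + 1} years of data"
        )
    marr = build_marray(dataset.histories)
    anchors = impute_initial_counts(
        dataset.counts, config.d, seed=config.mcmc.seed
    )
    return PosteriorSpec(
        marr=marr,
        pairs_monitored=dataset.pairs_monitored,
        chicks_fledged=dataset.chicks_fledged,
        counts=dataset.counts,
        years=dataset.years,
        anchors=anchors,
        config=config,
        colony_id=dataset.colony_id,
    )


DEFAULT_MONITORS = [
    "mu_phi", "mu_f", "mu_p", "alpha", "phi_im",
    "sig_phi", "sig_f", "sigma_p", "sigma_y", "cov_pf", "r",
    "phi", "f", "p", "N", "R", "S",
]

RHAT_THRESHOLD = 1.1


@dataclass
class PosteriorSamples:
    """Chain-indexed posterior draws plus convergence diagnostics."""

    posterior: dict[str, np.ndarray]
    years: np.ndarray
    formulation: Formulation
    d: int
    provenance: dict
    rhat: dict[str, np.ndarray] = field(default_factory=dict)
    converged: bool = True

    @property
    def n_chains(self) -> int:
        return next(iter(self.posterior.values())).shape[0]

    @property
    def n_draws(self) -> int:
        return next(iter(self.posterior.values())).shape[1]

    def stacked(self, name: str) -> np.ndarray:
        """Draws of one variable with chains concatenated."""
        arr = self.posterior[name]
        return arr.reshape(-1, *arr.shape[2:])

    def to_inferencedata(self):
        import arviz as az

        return az.from_dict(posterior=self.posterior)

    def summary(self, names=None) -> pd.DataFrame:
        rows = []
        for name in names or self.posterior:
            arr = self.posterior[name]
            flat = arr.reshape(-1, *arr.shape[2:])
            rh = self.rhat.get(name)
            if flat.ndim == 1:
                entries = [(name, flat, rh)]
            else:
                entries = [
                    (f"{name}[{i + 1}]", flat[:, i],
                     None if rh is None else np.atleast_1d(rh)[i])
                    for i in range(flat.shape[1])
                ]
            for label, draws, rhat in entries:
                draws = draws[~np.isnan(draws)]
                if draws.size == 0:
                    continue
                rows.append(
                    {
                        "parameter": label,
                        "mean": float(draws.mean()),
                        "ci_low": float(np.quantile(draws, 0.025)),
                        "ci_high": float(np.quantile(draws, 0.975)),
                        "rhat": float(rhat) if rhat is not None and np.isfinite(rhat) else np.nan,
                    }
                )
        return pd.DataFrame(rows)


def _compute_rhat(posterior: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    import arviz as az

    clean = {}
    for name, arr in posterior.items():
        if arr.ndim == 2:
            clean[name] = arr
        else:
            finite = np.isfinite(arr).all(axis=(0, 1))
            if finite.any():
                clean[name] = arr  # arviz tolerates NaN slices -> NaN rhat
    ds = az.rhat(az.from_dict(posterior=clean))
    return {name: np.asarray(ds[name].values) for name in clean}


def sample_posterior(
    spec: PosteriorSpec,
    mcmc: MCMCSettings | None = None,
    seed: int | None = None,
    monitors=None,
    prior_only: bool = False,
    compute_rhat: bool = True,
) -> PosteriorSamples:
    """Draw from the joint posterior with JAGS.

    Identical seed and settings give identical draws.  Non-convergence
    (any split-R-hat above 1.1) sets ``converged = False`` on the result
    rather than raising.
    """
    mcmc = mcmc or spec.config.mcmc
    if seed is not None:
        mcmc = MCMCSettings(
            n_chains=mcmc.n_chains, n_iter=mcmc.n_iter,
            n_burn=mcmc.n_burn, thin=mcmc.thin, seed=seed,
        )
    monitors = list(monitors) if monitors is not None else list(DEFAULT_MONITORS)
    if prior_only:
        monitors = [
            m for m in monitors
            if m in {"mu_phi", "mu_f", "mu_p", "alpha", "phi_im", "sig_phi",
                     "sig_f", "sigma_p", "cov_pf", "r", "phi", "f", "p"}
        ]
    draws = run_jags(
        model=spec.jags_model(prior_only=prior_only),
        data=spec.jags_data(prior_only=prior_only),
        inits=spec.jags_inits(mcmc.n_chains, mcmc.seed, prior_only=prior_only),
        monitors=monitors,
        n_iter=mcmc.n_iter,
        n_burn=mcmc.n_burn,
        thin=mcmc.thin,
    )
    rhat = _compute_rhat(draws) if compute_rhat else {}
    finite_rhats = np.concatenate(
        [np.atleast_1d(v)[np.isfinite(np.atleast_1d(v))] for v in rhat.values()]
    ) if rhat else np.array([])
    converged = bool(finite_rhats.size == 0 or finite_rhats.max() <= RHAT_THRESHOLD)
    provenance = {
        "colony_id": spec.colony_id,
        "engine": "JAGS (rjags via Rscript)",
        "latent_states": "discrete binomial latents, sampled directly",
        "formulation": spec.formulation.value,
        "n_chains": mcmc.n_chains,
        "n_iter": mcmc.n_iter,
        "n_burn": mcmc.n_burn,
        "thin": mcmc.thin,
        "seed": mcmc.seed,
        "prior_only": prior_only,
    }
    return PosteriorSamples(
        posterior=draws,
        years=spec.years,
        formulation=spec.formulation,
        d=spec.config.d,
        provenance=provenance,
        rhat=rhat,
        converged=converged,
    )


@dataclass(frozen=True)
class CorrelationSummary:
    """Posterior of the survival-productivity correlation r."""

    draws: np.ndarray
    mean: float
    ci_low: float
    ci_high: float
    prob_positive: float
    n_zero_variance: int = 0


def derive_correlation(
    samples: PosteriorSamples, strict_paper_wording: bool = False
) -> CorrelationSummary:
    """Summarise the demographic correlation from the posterior draws.

    The default divides the covariance of the annual survival and
    productivity deviations by the product of their SDs (the Pearson
    correlation, guaranteed to lie in [-1, 1]).  With
    ``strict_paper_wording=True`` the covariance is divided by the *sum*
    of the two temporal variances instead — an alternative scaled
    covariance reported for audit; it is not a correlation coefficient.
    """
    cov = samples.stacked("cov_pf")
    s1 = samples.stacked("sig_phi")
    s2 = samples.stacked("sig_f")
    denom = s1**2 + s2**2 if strict_paper_wording else s1 * s2
    zero = denom <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(zero, 0.0, cov / np.where(zero, 1.0, denom))
    if not strict_paper_wording:
        r = np.clip(r, -1.0, 1.0)
    return CorrelationSummary(
        draws=r,
        mean=float(r.mean()),
        ci_low=float(np.quantile(r, 0.025)),
        ci_high=float(np.quantile(r, 0.975)),
        prob_positive=float((r > 0).mean()),
        n_zero_variance=int(zero.sum()),
    )
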