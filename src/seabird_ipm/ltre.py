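"""Transient life-table response experiment for realised growth rates.

The realised annual growth rate of the breeding-female segment is
lambda_t = N_{t+1} / N_t.  Under the recruitment-at-age-d process it
satisfies, to first order,

    lambda_t = phi_t * (1 + 0.5 * phi_im * F'_t * q_t),

where phi_t is adult survival over t -> t+1, F'_t the productivity cohort
feeding the transition, q_t = N_{t+1-d} / N_t the population-structure
ratio, and phi_im the compound immature survival x philopatry.  The
variance of lambda_t over years is decomposed, per posterior draw, into
first-order contributions from the temporal variances of the time-varying
rates and from their covariances:

    contribution(theta_i, theta_j) = cov(theta_i, theta_j)
                                     * dlambda/dtheta_i * dlambda/dtheta_j

with sensitivities evaluated at the posterior-draw means of the rate
series.  Diagonal terms are variance contributions; off-diagonal pairs
(counted twice) are covariance contributions.  Scaled contributions
divide by the first-order total and therefore sum to one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import Formulation

TERMS = (
    "var_survival",
    "var_productivity",
    "var_structure",
    "cov_survival_productivity",
    "cov_survival_structure",
    "cov_productivity_structure",
)


def realized_lambda(N_draws: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-draw realised growth rates lambda_t = N_{t+1} / N_t.

    ``N_draws`` has shape (draws, years).  Draws whose trajectory touches
    zero population cannot define a growth rate and are excluded; the
    returned boolean mask flags the draws kept.
    """
    N = np.atleast_2d(np.asarray(N_draws, dtype=float))
    keep = (N > 0).all(axis=1)
    if not keep.any():
        raise ValueError("every trajectory hit zero population")
    lam = N[keep, 1:] / N[keep, :-1]
    return lam, keep


def lambda_expression(phi, f, q, phi_im):
    """First-order realised growth lambda = phi * (1 + 0.5 * phi_im * f * q)."""
    return phi * (1.0 + 0.5 * phi_im * f * q)


def lambda_sensitivities(mean_rates, phi_im: float) -> np.ndarray:
    """Analytic partials of lambda wrt (survival, productivity, structure).

    ``mean_rates`` = (mean survival, mean productivity, mean structure
    ratio q); the partials are evaluated at those means:

    * d lambda / d phi = 1 + 0.5 * phi_im * f * q
    * d lambda / d f   = 0.5 * phi * phi_im * q
    * d lambda / d q   = 0.5 * phi * phi_im * f
    """
    phi_bar, f_bar, q_bar = (float(x) for x in mean_rates)
    if not all(np.isfinite([phi_bar, f_bar, q_bar, phi_im])):
        raise ValueError("rate means must be finite")
    return np.array(
        [
            1.0 + 0.5 * phi_im * f_bar * q_bar,
            0.5 * phi_bar * phi_im * q_bar,
            0.5 * phi_bar * phi_im * f_bar,
        ]
    )


@dataclass(frozen=True)
class LTREResult:
    """Raw and scaled first-order contributions to var(lambda_t).

    ``contributions`` holds the per-draw raw terms (draws x 6, ordered as
    :data:`TERMS`, covariance terms already doubled); their row sums equal
    ``first_order_total``.  ``scaled`` divides by the per-draw first-order
    total (rows sum to 1).  ``empirical_var`` is the brute-force variance
    of lambda_t per draw, so ``first_order_total / empirical_var`` is an
    approximation-quality diagnostic.  ``degenerate`` flags draws whose
    rate series had zero variance (all contributions zero, scaled
    undefined and stored as NaN).
    """

    contributions: np.ndarray
    scaled: np.ndarray
    first_order_total: np.ndarray
    empirical_var: np.ndarray
    degenerate: np.ndarray
    formulation: Formulation
    demographic_only_scaled: np.ndarray | None = None

    def table(self) -> pd.DataFrame:
        rows = []
        ok = ~self.degenerate
        for k, term in enumerate(TERMS):
            raw = self.contributions[:, k]
            sc = self.scaled[ok, k]
            rows.append(
                {
                    "term": term,
                    "contribution": float(raw.mean()),
                    "contribution_ci_low": float(np.quantile(raw, 0.025)),
                    "contribution_ci_high": float(np.quantile(raw, 0.975)),
                    "scaled": float(sc.mean()) if sc.size else np.nan,
                    "scaled_ci_low": float(np.quantile(sc, 0.025)) if sc.size else np.nan,
                    "scaled_ci_high": float(np.quantile(sc, 0.975)) if sc.size else np.nan,
                }
            )
        rows.append(
            {
                "term": "first_order_total",
                "contribution": float(self.first_order_total.mean()),
                "contribution_ci_low": float(np.quantile(self.first_order_total, 0.025)),
                "contribution_ci_high": float(np.quantile(self.first_order_total, 0.975)),
                "scaled": 1.0,
                "scaled_ci_low": np.nan,
                "scaled_ci_high": np.nan,
            }
        )
        rows.append(
            {
                "term": "empirical_var_lambda",
                "contribution": float(self.empirical_var.mean()),
                "contribution_ci_low": float(np.quantile(self.empirical_var, 0.025)),
                "contribution_ci_high": float(np.quantile(self.empirical_var, 0.975)),
                "scaled": np.nan,
                "scaled_ci_low": np.nan,
                "scaled_ci_high": np.nan,
            }
        )
        return pd.DataFrame(rows)


def paired_series(phi, f, q, formulation: Formulation):
    """Align the three rate series at the formulation's cross-season lag.

    ``phi`` (draws x T-1) indexes survival over interval t -> t+1; ``f``
    (draws x T) productivity per year; ``q`` (draws x n_q) the structure
    ratio per transition, aligned with phi's trailing intervals.  Under
    PRE, survival over t-1 -> t pairs with productivity in year t; under
    POST productivity in year t pairs with survival over t -> t+1.
    """
    formulation = Formulation(formulation)
    n = q.shape[1]
    phi_tail = phi[:, -n:]
    if formulation is Formulation.PRE:
        f_paired = f[:, -n:]          # f year t+1 with interval t -> t+1
    else:
        f_paired = f[:, -n - 1:-1]    # f year t with interval t -> t+1
    return phi_tail, f_paired, q


def decompose_var_lambda(
    phi_draws: np.ndarray,
    f_draws: np.ndarray,
    q_draws: np.ndarray,
    phi_im_draws: np.ndarray,
    formulation: Formulation | str = Formulation.PRE,
    n_samples: int | None = 10_000,
    seed: int = 0,
    empirical_lambda: np.ndarray | None = None,
) -> LTREResult:
    """First-order decomposition of var(lambda_t), per posterior draw.

    Parameters are draw-indexed rate series (see :func:`paired_series`).
    ``n_samples`` posterior draws are used (subsampled with a fixed seed
    when more are available), matching common practice of decomposing on a
    posterior subsample.  ``empirical_lambda`` optionally supplies
    realised lambda_t series (draws x transitions) from latent N draws;
    otherwise the first-order lambda expression evaluated on the rate
    series is used for the empirical variance.
    """
    formulation = Formulation(formulation)
    phi_draws = np.atleast_2d(phi_draws)
    f_draws = np.atleast_2d(f_draws)
    q_draws = np.atleast_2d(q_draws)
    phi_im_draws = np.atleast_1d(phi_im_draws)
    n_draws = phi_draws.shape[0]
    if n_samples is not None and n_draws > n_samples:
        idx = np.random.default_rng(seed).choice(
            n_draws, size=n_samples, replace=False
        )
        idx.sort()
        phi_draws, f_draws, q_draws = (
            phi_draws[idx], f_draws[idx], q_draws[idx]
        )
        phi_im_draws = phi_im_draws[idx]
        if empirical_lambda is not None:
            empirical_lambda = np.atleast_2d(empirical_lambda)[idx]

    phi_s, f_s, q_s = paired_series(phi_draws, f_draws, q_draws, formulation)
    if phi_s.shape[1] < 2:
        raise ValueError("need at least 2 transitions to form variances")
    n_draws = phi_s.shape[0]
    contributions = np.zeros((n_draws, len(TERMS)))
    totals = np.zeros(n_draws)
    empirical = np.zeros(n_draws)
    degenerate = np.zeros(n_draws, dtype=bool)
    for k in range(n_draws):
        theta = np.vstack([phi_s[k], f_s[k], q_s[k]])
        means = theta.mean(axis=1)
        sens = lambda_sensitivities(means, float(phi_im_draws[k]))
        C = np.cov(theta)
        weighted = C * np.outer(sens, sens)
        contributions[k, 0:3] = np.diag(weighted)
        contributions[k, 3] = 2.0 * weighted[0, 1]
        contributions[k, 4] = 2.0 * weighted[0, 2]
        contributions[k, 5] = 2.0 * weighted[1, 2]
        totals[k] = contributions[k].sum()
        if empirical_lambda is None:
            lam = lambda_expression(
                phi_s[k], f_s[k], q_s[k], float(phi_im_draws[k])
            )
        else:
            lam = empirical_lambda[k]
        empirical[k] = lam.var(ddof=1)
        if totals[k] <= 0:
            degenerate[k] = True
    with np.errstate(divide="ignore", invalid="ignore"):
        scaled = contributions / totals[:, None]
    scaled[degenerate] = np.nan
    demo = contributions[:, [0, 1, 3]]
    demo_tot = demo.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        demo_scaled = demo / demo_tot[:, None]
    demo_scaled[demo_tot <= 0] = np.nan
    return LTREResult(
        contributions=contributions,
        scaled=scaled,
        first_order_total=totals,
        empirical_var=empirical,
        degenerate=degenerate,
        formulation=formulation,
        demographic_only_scaled=demo_scaled,
    )


def ltre_from_posterior(
    samples,
    n_samples: int | None = 10_000,
    seed: int = 0,
) -> LTREResult:
    """Run the decomposition on a fitted model's posterior draws.

    Uses the latent N draws for the structure ratio q_t = N_{t+1-d} / N_t
    and for the empirical var(lambda_t), and the monitored annual rate
    series for the theta vector.
    """
    phi = samples.stacked("phi")
    f = samples.stacked("f")
    N = samples.stacked("N")
    phi_im = samples.stacked("phi_im")
    d = samples.d
    T = N.shape[1]
    # transitions t -> t+1 for t = d .. T-2 (0-based): q needs N_{t+1-d}
    t_idx = np.arange(d, T - 1)
    q = N[:, t_idx + 1 - d] / N[:, t_idx]
    lam = N[:, t_idx + 1] / N[:, t_idx]
    phi_int = phi[:, t_idx]           # interval t -> t+1
    return decompose_var_lambda(
        phi_draws=phi_int,
        f_draws=f,
        q_draws=q,
        phi_im_draws=phi_im,
        formulation=samples.formulation,
        n_samples=n_samples,
        seed=seed,
        empirical_lambda=lam,
    )
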