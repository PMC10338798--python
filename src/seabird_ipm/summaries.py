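"""Headline derived quantities: mean growth, trends, annualised rates."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class IntervalSummary:
    mean: float
    ci_low: float
    ci_high: float

    def round(self, decimals: int = 2) -> tuple[float, float, float]:
        return (
            round(self.mean, decimals),
            round(self.ci_low, decimals),
            round(self.ci_high, decimals),
        )


def _summarise(draws: np.ndarray) -> IntervalSummary:
    return IntervalSummary(
        mean=float(np.mean(draws)),
        ci_low=float(np.quantile(draws, 0.025)),
        ci_high=float(np.quantile(draws, 0.975)),
    )


def geometric_mean_lambda(lambda_draws: np.ndarray) -> IntervalSummary:
    """Geometric-mean annual growth per draw, summarised over draws.

    For each draw, (prod_t lambda_t)^(1/(T-1)) — identically
    (N_T / N_1)^(1/(T-1)) by telescoping.  Draws containing non-positive
    growth rates cannot form a geometric mean and are excluded.
    """
    lam = np.atleast_2d(np.asarray(lambda_draws, dtype=float))
    keep = (lam > 0).all(axis=1)
    if not keep.any():
        raise ValueError("no draw has an all-positive growth series")
    g = np.exp(np.log(lam[keep]).mean(axis=1))
    return _summarise(g)


def annual_rate_from_combined(compound, n_years: int):
    """Annualise a compound probability: rate = compound**(1 / n_years).

    Applied per posterior draw so credible intervals transform
    consistently.  For immature survival combined over the d - 1 years
    from fledging to the year before recruitment, ``n_years = d - 1``.
    """
    compound = np.asarray(compound, dtype=float)
    if n_years < 1:
        raise ValueError("n_years must be >= 1")
    if ((compound <= 0) | (compound >= 1)).any():
        raise ValueError("compound probability must lie in (0, 1)")
    out = compound ** (1.0 / n_years)
    return float(out) if out.ndim == 0 else out


def trend_slope(lambda_draws: np.ndarray, years) -> IntervalSummary:
    """OLS slope of lambda_t on calendar year, per draw.

    ``years`` are the calendar years of the transitions (length matching
    the lambda series).  The slope is invariant to re-centering the years.
    """
    lam = np.atleast_2d(np.asarray(lambda_draws, dtype=float))
    years = np.asarray(years, dtype=float)
    if years.shape[0] != lam.shape[1]:
        raise ValueError("years must match the lambda series length")
    if years.shape[0] < 3:
        raise ValueError("need at least 3 years for a trend")
    x = years - years.mean()
    slopes = lam @ x / (x @ x)
    return _summarise(slopes)


def summary_report(
    posterior,
    ltre_result,
    correlation,
    decimals: int = 2,
) -> dict:
    """Assemble the per-colony headline report as a plain dict.

    Combines the posterior of mean survival/productivity, the compound
    and annualised immature survival, the trap-dependence offset, the
    demographic correlation, realised-growth summaries and the LTRE
    table.  Full precision is kept under ``"full"``; rounded values (to
    ``decimals``) under ``"rounded"``.
    """
    from .ltre import realized_lambda

    N = posterior.stacked("N")
    lam, _ = realized_lambda(N)
    years = np.asarray(posterior.years)
    gmean = geometric_mean_lambda(lam)
    slope = trend_slope(lam, years[:-1])
    phi_im = posterior.stacked("phi_im")
    annual_im = annual_rate_from_combined(phi_im, posterior.d - 1)

    full = {
        "colony_id": posterior.provenance.get("colony_id"),
        "formulation": posterior.formulation.value,
        "adult_survival": vars(_summarise(posterior.stacked("phi").mean(axis=1))),
        "productivity": vars(_summarise(posterior.stacked("f").mean(axis=1))),
        "resighting": vars(_summarise(posterior.stacked("p").mean(axis=1))),
        "trap_dependence_alpha": vars(_summarise(posterior.stacked("alpha"))),
        "immature_survival_compound": vars(_summarise(phi_im)),
        "immature_survival_annual": vars(_summarise(annual_im)),
        "correlation_r": {
            "mean": correlation.mean,
            "ci_low": correlation.ci_low,
            "ci_high": correlation.ci_high,
            "prob_positive": correlation.prob_positive,
        },
        "geometric_mean_lambda": vars(gmean),
        "trend_slope": vars(slope),
        "converged": bool(posterior.converged),
    }
    if ltre_result is not None:
        full["ltre"] = ltre_result.table().to_dict(orient="records")

    def _round(obj):
        if isinstance(obj, float):
            return round(obj, decimals)
        if isinstance(obj, dict):
            return {k: _round(v) for k, v in obj.items()}
        if isinstance(obj, list):
            return [_round(v) for v in obj]
        return obj

    return {"full": full, "rounded": _round(full)}
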