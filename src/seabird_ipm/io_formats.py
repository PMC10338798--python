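"""Reading, validating and writing the three colony data streams.

A colony contributes three annual data streams over a common span of
calendar years: individual capture-mark-resight histories (wide binary
CSV, one 0/1 column per year), productivity trials (monitored pairs and
fledged chicks per year), and breeding-pair counts (possibly with missing
years — encoded as empty fields, never 0, since a count of zero is
meaningful).  Reports (posterior summaries and the LTRE table) are written
as CSV plus JSON and round-trip exactly at the stored precision.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .synthetic import Formulation

MISSING = float("nan")


class ValidationError(ValueError):
    """A data stream violates a colony-dataset invariant."""


@dataclass(frozen=True)
class ColonyDataset:
    """The three joint data streams for one colony, year-aligned.

    ``years`` are consecutive calendar years; ``histories`` has one column
    per year; ``pairs_monitored``/``chicks_fledged`` and ``counts`` have
    one entry per year (``counts`` uses NaN for missing census years).
    """

    colony_id: str
    years: np.ndarray
    histories: np.ndarray
    pairs_monitored: np.ndarray
    chicks_fledged: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.validate()

    @property
    def n_years(self) -> int:
        return int(self.years.shape[0])

    def validate(self) -> None:
        T = self.years.shape[0]
        if np.any(np.diff(self.years) != 1):
            raise ValidationError("years must be consecutive calendar years")
        if self.histories.shape[1] != T:
            raise ValidationError(
                "histories must have one occasion column per year"
            )
        if not np.isin(self.histories, (0, 1)).all():
            raise ValidationError("histories must contain only 0/1")
        empty = np.flatnonzero(self.histories.sum(axis=1) == 0)
        if empty.size:
            raise ValidationError(
                f"history rows with no capture: {empty[:5].tolist()}"
            )
        for arr, name in (
            (self.pairs_monitored, "pairs_monitored"),
            (self.chicks_fledged, "chicks_fledged"),
        ):
            if arr.shape[0] != T:
                raise ValidationError(f"{name} must have one entry per year")
            if (arr < 0).any():
                raise ValidationError(f"{name} must be non-negative")
        bad = np.flatnonzero(self.chicks_fledged > self.pairs_monitored)
        if bad.size:
            raise ValidationError(
                "more chicks fledged than pairs monitored in year(s) "
                f"{self.years[bad].tolist()}"
            )
        if self.counts.shape[0] != T:
            raise ValidationError("counts must have one entry per year")
        observed = self.counts[~np.isnan(self.counts)]
        if (observed < 0).any():
            raise ValidationError("counts must be non-negative")
        if observed.size < 2:
            raise ValidationError("need at least 2 non-missing counts")


def read_colony_dataset(
    histories_path,
    productivity_path,
    counts_path,
    colony_id: str | None = None,
) -> ColonyDataset:
    """Read and validate the three CSV streams.

    ``histories.csv``: column ``id`` then one 0/1 column per calendar year.
    ``productivity.csv``: ``year, pairs_monitored, chicks_fledged``.
    ``counts.csv``: ``year, count`` with empty fields for missing censuses.
    """
    hist = pd.read_csv(histories_path)
    if hist.columns[0] != "id":
        raise ValidationError("histories.csv must start with an 'id' column")
    try:
        years = np.array([int(c) for c in hist.columns[1:]])
    except ValueError as exc:
        raise ValidationError(f"occasion columns must be years: {exc}") from None
    histories = hist.iloc[:, 1:].to_numpy()
    if np.isnan(histories.astype(float)).any():
        raise ValidationError("histories must not contain missing entries")
    histories = histories.astype(np.int8)

    prod = pd.read_csv(productivity_path)
    for col in ("year", "pairs_monitored", "chicks_fledged"):
        if col not in prod.columns:
            raise ValidationError(f"productivity.csv misses column {col!r}")
    prod = prod.set_index("year").reindex(years)
    if prod.isna().any().any():
        missing = prod.index[prod.isna().any(axis=1)].tolist()
        raise ValidationError(f"productivity misses year(s) {missing}")

    cnt = pd.read_csv(counts_path)
    for col in ("year", "count"):
        if col not in cnt.columns:
            raise ValidationError(f"counts.csv misses column {col!r}")
    extra = set(cnt["year"]) - set(years.tolist())
    if extra:
        raise ValidationError(f"count year(s) outside declared range: {sorted(extra)}")
    counts = cnt.set_index("year")["count"].reindex(years).to_numpy(dtype=float)

    return ColonyDataset(
        colony_id=colony_id or Path(histories_path).parent.name,
        years=years,
        histories=histories,
        pairs_monitored=prod["pairs_monitored"].to_numpy(dtype=np.int64),
        chicks_fledged=prod["chicks_fledged"].to_numpy(dtype=np.int64),
        counts=counts,
    )


def write_colony_dataset(dataset: ColonyDataset, out_dir) -> dict[str, Path]:
    """Write the three CSV streams (inverse of :func:`read_colony_dataset`)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "histories": out / "histories.csv",
        "productivity": out / "productivity.csv",
        "counts": out / "counts.csv",
    }
    hist = pd.DataFrame(
        dataset.histories, columns=[str(y) for y in dataset.years]
    )
    hist.insert(0, "id", np.arange(1, dataset.histories.shape[0] + 1))
    hist.to_csv(paths["histories"], index=False)
    pd.DataFrame(
        {
            "year": dataset.years,
            "pairs_monitored": dataset.pairs_monitored,
            "chicks_fledged": dataset.chicks_fledged,
        }
    ).to_csv(paths["productivity"], index=False)
    pd.DataFrame({"year": dataset.years, "count": dataset.counts}).to_csv(
        paths["counts"], index=False
    )
    return paths


@dataclass(frozen=True)
class MCMCSettings:
    """Sampler settings; totals are per chain, burn-in included."""

    n_chains: int = 3
    n_iter: int = 20_000
    n_burn: int = 5_000
    thin: int = 2
    seed: int = 1

    def __post_init__(self) -> None:
        if self.n_burn >= self.n_iter:
            raise ValidationError("burn-in must be shorter than the chain")

    @classmethod
    def paper_scale(cls, seed: int = 1) -> "MCMCSettings":
        """Publication-scale settings: 3 x 500,000, 50,000 burn-in, thin 10."""
        return cls(n_chains=3, n_iter=500_000, n_burn=50_000, thin=10, seed=seed)


@dataclass(frozen=True)
class PriorConfig:
    """Weakly informative default priors (SDs, ranges)."""

    mean_sd: float = 10.0          # logit-scale means and alpha
    loading_sd: float = 2.0        # Cholesky loading / scale half-normals
    sigma_p_upper: float = 3.0
    sigma_y_upper_factor: float = 10.0  # x max observed count
    init_n_cv: float = 0.2         # SD of anchor-year priors as share of anchor


@dataclass(frozen=True)
class RunConfig:
    """Everything a model run needs besides the data."""

    formulation: Formulation = Formulation.PRE
    d: int = 5
    b: float = 1.0
    mcmc: MCMCSettings = field(default_factory=MCMCSettings)
    priors: PriorConfig = field(default_factory=PriorConfig)
    report_decimals: int = 2

    def __post_init__(self) -> None:
        if self.d < 2:
            raise ValidationError("age at first breeding must be >= 2")
        if not (0 < self.b <= 1):
            raise ValidationError("breeding propensity must lie in (0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        if "formulation" in raw:
            kwargs["formulation"] = Formulation(raw["formulation"])
        for key in ("d", "b", "report_decimals"):
            if key in raw:
                kwargs[key] = raw[key]
        if "mcmc" in raw:
            kwargs["mcmc"] = MCMCSettings(**raw["mcmc"])
        if "priors" in raw:
            kwargs["priors"] = PriorConfig(**raw["priors"])
        return cls(**kwargs)


def write_reports(posterior, ltre, out_dir) -> dict[str, Path]:
    """Write the posterior summary and LTRE tables (CSV + JSON).

    ``posterior`` is a :class:`~seabird_ipm.ipm.PosteriorSamples`; ``ltre``
    an :class:`~seabird_ipm.ltre.LTREResult` (or None to skip).  Values are
    written at full double precision so a round-trip reproduces them
    bit-for-bit.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    summary = posterior.summary()
    paths["summary_csv"] = out / "posterior_summary.csv"
    summary.to_csv(paths["summary_csv"], index=False, float_format="%.17g")
    paths["summary_json"] = out / "posterior_summary.json"
    payload = {
        "colony_id": posterior.provenance.get("colony_id"),
        "formulation": posterior.formulation.value,
        "converged": bool(posterior.converged),
        "provenance": posterior.provenance,
        "parameters": summary.to_dict(orient="records"),
    }
    paths["summary_json"].write_text(json.dumps(payload, indent=2))

    if ltre is not None:
        table = ltre.table()
        paths["ltre_csv"] = out / "ltre_contributions.csv"
        table.to_csv(paths["ltre_csv"], index=False, float_format="%.17g")
    return paths


def read_summary(path) -> pd.DataFrame:
    """Re-read a posterior summary CSV written by :func:`write_reports`."""
    return pd.read_csv(path)
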