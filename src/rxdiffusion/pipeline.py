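"""End-to-end cohort pipeline: ingest -> preprocess -> fit -> results table.

Ties the per-drug pieces together for whole-cohort runs, with explicit
exclusion reporting: a drug that cannot be preprocessed or fitted is
carried through as an exclusion record with a reason code, never silently
dropped.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from datetime import datetime, timezone

import numpy as np
import pandas as pd

from . import __version__
from .model import BassDiffusionModel, FitConfig
from .preprocess import (
    EmptySeriesError,
    MonthlySeries,
    monthly_population,
    to_normalized,
)
from .simulate import ConfigError, SimulationConfig

logger = logging.getLogger("rxdiffusion")

__all__ = [
    "PipelineConfig",
    "RunManifest",
    "read_prescriptions",
    "read_population",
    "build_monthly_series",
    "fit_cohort",
    "format_published_style",
]

RESULT_COLUMNS = [
    "drug_id",
    "first_month",
    "n_obs",
    "p",
    "q",
    "m",
    "pq_ratio",
    "r2",
    "adjusted_r2",
    "adoption_time_months",
    "adoption_time_years",
    "peak_time_months",
    "classification",
    "converged",
    "left_censored",
]


@dataclass(frozen=True)
class PipelineConfig:
    """Validated configuration for the fit/simulate pipeline.

    ``window`` is the smoothing span in months (odd); ``saturation_fraction``
    sets the adoption-time convention; ``simulation`` is the generator
    block used by the ``simulate`` command.
    """

    window: int = 13
    smoothing_mode: str = "centered"
    saturation_fraction: float = 0.95
    min_obs: int = 12
    seed: int = 0
    fit: FitConfig = field(default_factory=FitConfig)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    def __post_init__(self) -> None:
        if self.window < 1 or self.window % 2 == 0:
            raise ConfigError(f"window must be odd and >= 1, got {self.window}")
        if self.smoothing_mode not in ("centered", "trailing"):
            raise ConfigError(f"unknown smoothing_mode {self.smoothing_mode!r}")
        if not 0 < self.saturation_fraction < 1:
            raise ConfigError(
                f"saturation_fraction must be in (0, 1), got {self.saturation_fraction}"
            )
        if self.min_obs < 6:
            raise ConfigError("min_obs must be >= 6")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        """Build from a (YAML-loaded) mapping, rejecting unknown keys."""
        d = dict(d or {})
        kwargs: dict = {}
        known = {f for f in cls.__dataclass_fields__}
        for key in d:
            if key not in known:
                raise ConfigError(f"unknown config key: {key!r}")
        for key in ("window", "smoothing_mode", "saturation_fraction", "min_obs", "seed"):
            if key in d:
                kwargs[key] = d[key]
        if "fit" in d:
            sub = d["fit"]
            unknown = set(sub) - set(FitConfig.__dataclass_fields__)
            if unknown:
                raise ConfigError(f"unknown config key: fit.{sorted(unknown)[0]!r}")
            kwargs["fit"] = FitConfig(**{
                k: tuple(v) if isinstance(v, list) else v for k, v in sub.items()
            })
        if "simulation" in d:
            sub = d["simulation"]
            unknown = set(sub) - set(SimulationConfig.__dataclass_fields__)
            if unknown:
                raise ConfigError(f"unknown config key: simulation.{sorted(unknown)[0]!r}")
            kwargs["simulation"] = SimulationConfig(**{
                k: tuple(v) if isinstance(v, list) else v for k, v in sub.items()
            })
        try:
            return cls(**kwargs)
        except TypeError as exc:  # wrong value type for a known key
            raise ConfigError(str(exc)) from exc

    def with_seed(self, seed: int) -> "PipelineConfig":
        return replace(self, seed=seed, simulation=replace(self.simulation, seed=seed))

    def to_dict(self) -> dict:
        return asdict(self)

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    """Provenance record emitted next to every pipeline output."""

    command: str
    config_hash: str
    version: str
    seed: int
    created_utc: str
    row_counts: dict
    exclusions: list

    @classmethod
    def create(cls, command: str, config: PipelineConfig, row_counts: dict,
               exclusions: list | None = None) -> "RunManifest":
        return cls(
            command=command,
            config_hash=config.content_hash(),
            version=__version__,
            seed=config.seed,
            created_utc=datetime.now(timezone.utc).isoformat(timespec="seconds"),
            row_counts=row_counts,
            exclusions=exclusions or [],
        )

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)
            fh.write("\n")


def read_prescriptions(path) -> pd.DataFrame:
    """Read a long-format prescriptions CSV: drug_id, month (YYYY-MM), count.

    Multiple rows for one (drug_id, month) — e.g. several dosage forms of
    one medicine — are aggregated by summation.
    """
    df = pd.read_csv(path)
    required = {"drug_id", "month", "count"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"prescriptions CSV missing columns: {sorted(missing)}")
    if df.empty:
        raise ValueError(f"prescriptions file {path} contains no rows")
    df["month"] = pd.PeriodIndex(df["month"], freq="M")
    return (
        df.groupby(["drug_id", "month"], as_index=False, observed=True)["count"].sum()
    )


def read_population(path) -> pd.Series:
    """Read a population CSV with columns (month | year, persons)."""
    df = pd.read_csv(path)
    if "persons" not in df.columns:
        raise ValueError("population CSV must have a 'persons' column")
    if "month" in df.columns:
        idx = pd.PeriodIndex(df["month"], freq="M")
    elif "year" in df.columns:
        idx = pd.Index(df["year"].astype(int))
    else:
        raise ValueError("population CSV must have a 'month' or 'year' column")
    return pd.Series(df["persons"].to_numpy(dtype=float), index=idx)


def build_monthly_series(
    prescriptions: pd.DataFrame, population: pd.Series
) -> list[MonthlySeries]:
    """Assemble per-drug MonthlySeries over each drug's full observed span.

    Gaps inside a drug's span are filled with zero counts; the population
    series is aligned (and, for annual input, interpolated) to the same
    months.
    """
    out: list[MonthlySeries] = []
    for drug_id, g in prescriptions.groupby("drug_id", sort=True):
        months = pd.period_range(g["month"].min(), g["month"].max(), freq="M")
        counts = (
            g.set_index("month")["count"].reindex(months, fill_value=0).to_numpy(dtype=float)
        )
        pop = monthly_population(population, months)
        out.append(
            MonthlySeries(
                drug_id=str(drug_id),
                start_month=months[0],
                counts=counts,
                population=pop,
            )
        )
    return out


def fit_cohort(
    series_list: list[MonthlySeries], config: PipelineConfig | None = None
) -> tuple[pd.DataFrame, list[dict]]:
    """Preprocess and fit every drug; return (results table, exclusions).

    Each exclusion is ``{"drug_id", "reason"}`` with reason codes
    ``no_prescriptions`` (all-zero series), ``too_short`` (fewer than
    ``min_obs`` months from onset) or ``unfittable``.
    """
    cfg = config or PipelineConfig()
    fit_cfg = replace(cfg.fit, saturation_fraction=cfg.saturation_fraction)
    rows: list[dict] = []
    exclusions: list[dict] = []

    def _exclude(drug_id: str, reason: str) -> None:
        logger.warning("excluding %s: %s", drug_id, reason)
        exclusions.append({"drug_id": drug_id, "reason": reason})

    for series in series_list:
        try:
            norm = to_normalized(series, window=cfg.window, mode=cfg.smoothing_mode)
        except EmptySeriesError:
            _exclude(series.drug_id, "no_prescriptions")
            continue
        if len(norm) < cfg.min_obs:
            _exclude(series.drug_id, "too_short")
            continue
        try:
            res = BassDiffusionModel.from_series(norm).fit(fit_cfg)
        except Exception as exc:  # pragma: no cover - defensive
            _exclude(series.drug_id, f"unfittable: {exc}")
            continue
        s = res.adoption_summary()
        rows.append(
            {
                "drug_id": series.drug_id,
                "first_month": str(norm.t0_month),
                "n_obs": res.nobs,
                "p": res.params.p,
                "q": res.params.q,
                "m": res.params.m,
                "pq_ratio": res.pq_ratio,
                "r2": res.rsquared,
                "adjusted_r2": res.rsquared_adj,
                "adoption_time_months": s.adoption_time_months,
                "adoption_time_years": s.adoption_time_years,
                "peak_time_months": s.peak_time_months,
                "classification": res.classification,
                "converged": res.converged,
                "left_censored": norm.left_censored,
            }
        )
    return pd.DataFrame(rows, columns=RESULT_COLUMNS), exclusions


def format_published_style(results: pd.DataFrame) -> pd.DataFrame:
    """Render a results table in the published per-drug layout.

    Columns: drug, first month as "MMM YYYY", saturation level, p/q ratio
    in scientific notation, R^2 to 3 decimals, adoption time in years to
    2 decimals.
    """
    months = pd.PeriodIndex(results["first_month"], freq="M")
    return pd.DataFrame(
        {
            "drug": results["drug_id"],
            "first_month": [m.strftime("%b %Y") for m in months],
            "max_monthly_per_100k": results["m"].round(0).astype(int),
            "pq_ratio": [f"{r:.2e}" for r in results["pq_ratio"]],
            "r2": results["adjusted_r2"].round(3),
            "adoption_time_years": results["adoption_time_years"].round(2),
        }
    )
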