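"""Synthetic national prescription-volume cohorts with known Bass truth.

The national drug-utilisation series this package targets are not public,
so simulated cohorts stand in for them in every test of the pipeline.  A
simulated drug is a monthly count series whose mean follows a Bass
adoption curve scaled to the (growing) national population, modulated by
multiplicative within-year seasonality and an end-of-calendar-year
safety-net spike, with Poisson or negative-binomial counting noise on top.

Ground-truth parameters are returned alongside each cohort so that
parameter-recovery and classification-accuracy experiments can score the
pipeline against the generating truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .bass import adoption_time, bass_cumulative, classify_adoption
from .preprocess import MonthlySeries

__all__ = ["ConfigError", "SimulationConfig", "TruthRecord", "simulate_drug", "simulate_cohort"]


class ConfigError(ValueError):
    """Raised for an invalid simulation configuration."""


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition defaults for a simulated prescribing cohort.

    The defaults mirror the corpus the analysis was designed for: 103
    drugs observed monthly over an 18-year window (216 months), a starting
    population of 17.5 million growing 1.2% per year, onset months spread
    through the first ten years, and roughly 19/103 of drugs external-
    dominant.  ``p``/``q`` are drawn log-uniformly over [1e-3, 0.3] per
    month, spanning the range implied by fitted national adoptions;
    saturation levels ``m`` are log-uniform over [10, 3000] per-100k.
    Seasonality defaults (10% sinusoidal amplitude, 1.25x December
    safety-net spike) are plausible placeholders, configurable, not
    estimates.
    """

    n_drugs: int = 103
    seed: int = 0
    p_range: tuple[float, float] = (1e-3, 0.3)
    q_range: tuple[float, float] = (1e-3, 0.3)
    m_range: tuple[float, float] = (10.0, 3000.0)
    span_months: int = 216
    onset_range: tuple[int, int] = (0, 120)
    start_month: str = "1992-01"
    seasonal_amplitude: float = 0.10
    december_multiplier: float = 1.25
    noise_model: str = "poisson"  # "poisson" | "negative_binomial" | "none"
    dispersion: float = 10.0  # NB shape; larger -> closer to Poisson
    population_start: float = 17.5e6
    population_growth: float = 0.012  # fraction per year
    external_share: float = 19 / 103

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in ("p_range", "q_range", "m_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ConfigError(f"{name} must satisfy 0 < lo <= hi, got {(lo, hi)}")
        if self.n_drugs < 1:
            raise ConfigError(f"n_drugs must be >= 1, got {self.n_drugs}")
        if not 0 <= self.seasonal_amplitude < 1:
            raise ConfigError(
                f"seasonal_amplitude must be in [0, 1), got {self.seasonal_amplitude}"
            )
        if self.december_multiplier < 1:
            raise ConfigError(
                f"december_multiplier must be >= 1, got {self.december_multiplier}"
            )
        if self.noise_model not in ("poisson", "negative_binomial", "none"):
            raise ConfigError(f"unknown noise_model {self.noise_model!r}")
        if self.noise_model == "negative_binomial" and self.dispersion <= 0:
            raise ConfigError("dispersion must be positive")
        lo, hi = self.onset_range
        if not (0 <= lo <= hi < self.span_months):
            raise ConfigError(f"onset_range must lie within the span, got {(lo, hi)}")
        if self.span_months < 24:
            raise ConfigError("span_months must be >= 24")
        if self.population_start <= 0:
            raise ConfigError("population_start must be positive")
        if not 0 <= self.external_share <= 1:
            raise ConfigError("external_share must be in [0, 1]")


@dataclass(frozen=True)
class TruthRecord:
    """Generating parameters of one simulated drug."""

    drug_id: str
    p: float
    q: float
    m: float
    onset: int
    onset_month: pd.Period
    adoption_time_months: float
    adoption_time_years: float
    classification: str


def _population(config: SimulationConfig) -> np.ndarray:
    t = np.arange(config.span_months, dtype=float)
    return config.population_start * (1.0 + config.population_growth) ** (t / 12.0)


def _seasonal_factor(config: SimulationConfig) -> np.ndarray:
    months = pd.period_range(config.start_month, periods=config.span_months, freq="M")
    phase = 2.0 * math.pi * (months.month - 1) / 12.0
    s = 1.0 + config.seasonal_amplitude * np.sin(phase)
    s = np.where(months.month == 12, s * config.december_multiplier, s)
    return s


def expected_counts(
    p: float, q: float, m: float, onset: int, config: SimulationConfig
) -> np.ndarray:
    """Noise-free mean count per month: m F(t - onset) pop_t/1e5 s_t."""
    t = np.arange(config.span_months, dtype=float)
    F = np.zeros_like(t)
    post = t >= onset
    F[post] = bass_cumulative(p, q, t[post] - onset)
    return m * F * (_population(config) / 1e5) * _seasonal_factor(config)


def simulate_drug(
    p: float,
    q: float,
    m: float,
    onset: int,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    drug_id: str = "drug",
) -> MonthlySeries:
    """Draw one monthly prescription series from the generative model.

    Counts before ``onset`` are exactly zero.  With ``noise_model="none"``
    counts equal the (real-valued) expected counts; Poisson noise draws
    integer counts at the expected mean; negative-binomial noise uses a
    gamma-Poisson mixture with shape ``dispersion``.
    """
    mean = expected_counts(p, q, m, onset, config)
    if config.noise_model == "none":
        counts = mean
    else:
        if rng is None:
            rng = np.random.default_rng(config.seed)
        if config.noise_model == "poisson":
            counts = rng.poisson(mean).astype(float)
        else:
            lam = np.where(mean > 0, rng.gamma(config.dispersion, mean / config.dispersion), 0.0)
            counts = rng.poisson(lam).astype(float)
    return MonthlySeries(
        drug_id=drug_id,
        start_month=pd.Period(config.start_month, freq="M"),
        counts=counts,
        population=_population(config),
    )


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[list[MonthlySeries], list[TruthRecord]]:
    """Simulate a cohort of drugs with known ground truth.

    For each drug, (p, q) are drawn log-uniformly from their ranges; a
    Bernoulli(``external_share``) draw decides whether the pair is
    oriented external-dominant (p > q) or internal-dominant (p < q), by
    swapping when needed.  Per-drug random substreams are derived
    deterministically from ``(seed, drug index)``, so cohorts are
    reproducible and individual drugs are independent of cohort size.
    """
    start = pd.Period(config.start_month, freq="M")
    series: list[MonthlySeries] = []
    truths: list[TruthRecord] = []
    for i in range(config.n_drugs):
        rng = np.random.default_rng([config.seed, i])
        p = math.exp(rng.uniform(*np.log(config.p_range)))
        q = math.exp(rng.uniform(*np.log(config.q_range)))
        want_external = rng.uniform() < config.external_share
        if want_external != (p > q):
            p, q = q, p
        if p == q:  # ties count as internal-dominant; nudge if external wanted
            if want_external:
                p *= 1.0 + 1e-9
        m = math.exp(rng.uniform(*np.log(config.m_range)))
        onset = int(rng.integers(config.onset_range[0], config.onset_range[1] + 1))
        drug_id = f"drug_{i:03d}"
        series.append(simulate_drug(p, q, m, onset, config, rng=rng, drug_id=drug_id))
        months = adoption_time(p, q, 0.95)
        truths.append(
            TruthRecord(
                drug_id=drug_id,
                p=p,
                q=q,
                m=m,
                onset=onset,
                onset_month=start + onset,
                adoption_time_months=months,
                adoption_time_years=months / 12.0,
                classification=classify_adoption(p, q),
            )
        )
    return series, truths


def truth_frame(truths: list[TruthRecord]) -> pd.DataFrame:
    """Truth records as a DataFrame (onset_month serialised YYYY-MM)."""
    df = pd.DataFrame([asdict(t) for t in truths])
    df["onset_month"] = df["onset_month"].astype(str)
    return df
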