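"""Raw monthly prescription counts -> smoothed per-100k adoption series.

Raw national prescription volumes carry seasonal structure and end-of-year
safety-net spikes that are nuisance variation for curve fitting.  The
preparation applied here is deliberately minimal: a moving average taken
over the non-zero values only, followed by normalisation to prescriptions
per 100,000 population, and truncation so that t = 0 is the month of the
first recorded prescription.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MonthlySeries",
    "NormalizedSeries",
    "EmptySeriesError",
    "smooth_nonzero",
    "normalize_per_capita",
    "to_normalized",
    "monthly_population",
]


class EmptySeriesError(ValueError):
    """Raised when a series contains no prescriptions at all."""


@dataclass
class MonthlySeries:
    """Raw per-drug monthly prescription counts with matching population.

    ``counts`` may be float-valued (noise-free simulated means); observed
    data are non-negative integers.  ``population`` is the national
    population in the same months.  Months are consecutive starting at
    ``start_month``.
    """

    drug_id: str
    start_month: pd.Period
    counts: np.ndarray
    population: np.ndarray

    def __post_init__(self) -> None:
        self.start_month = pd.Period(self.start_month, freq="M")
        self.counts = np.asarray(self.counts, dtype=float)
        self.population = np.asarray(self.population, dtype=float)
        if self.counts.ndim != 1 or self.counts.size == 0:
            raise ValueError("counts must be a non-empty 1-d sequence")
        if self.counts.shape != self.population.shape:
            raise ValueError("counts and population must have equal length")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if np.any(self.population <= 0):
            raise ValueError("population must be positive everywhere")

    @property
    def months(self) -> pd.PeriodIndex:
        return pd.period_range(self.start_month, periods=self.counts.size, freq="M")

    def __len__(self) -> int:
        return self.counts.size


@dataclass
class NormalizedSeries:
    """Smoothed prescriptions per 100,000 population, t = 0 at onset.

    ``t0_month`` is the calendar month of the first non-zero count and
    ``values[i]`` the smoothed per-100k volume i months later.  Adoption
    is taken to begin at the *start* of ``t0_month``, so the model time
    attached to ``values[i]`` is ``t = i + 1`` months of accrual (the
    ``t`` property); a month's volume reflects the adoption reached by
    its end.  ``left_censored`` flags drugs already prescribed in the
    very first observed month, whose true onset may predate the data.
    """

    drug_id: str
    t0_month: pd.Period
    values: np.ndarray
    window: int
    left_censored: bool = False

    def __post_init__(self) -> None:
        self.t0_month = pd.Period(self.t0_month, freq="M")
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("normalized values must be non-negative")

    @property
    def t(self) -> np.ndarray:
        """Model time grid in months since adoption onset: 1, 2, ..., n."""
        return np.arange(1, self.values.size + 1, dtype=float)

    def __len__(self) -> int:
        return self.values.size


def smooth_nonzero(counts, window: int, mode: str = "centered") -> np.ndarray:
    """Moving average taken over the non-zero values of a count series.

    The non-zero entries are compacted into a subsequence, smoothed with a
    moving average (windows truncating at the ends), and scattered back to
    their original positions; zero months (leading, interior or trailing)
    are left at zero and never enter any averaging set.

    Parameters
    ----------
    window : int
        Odd window length, >= 1, counted over non-zero entries.
        ``window=1`` is the identity.
    mode : {"centered", "trailing"}
        A centered window spans ``window // 2`` non-zero entries either
        side; a trailing window spans the ``window`` non-zero entries
        ending at the current one.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 1, got {window}")
    if mode not in ("centered", "trailing"):
        raise ValueError(f"mode must be 'centered' or 'trailing', got {mode!r}")
    x = np.asarray(counts, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("counts must be a non-empty 1-d sequence")
    out = np.zeros_like(x)
    idx = np.flatnonzero(x != 0)
    vals = x[idx]
    half = window // 2
    for j in range(vals.size):
        if mode == "centered":
            lo, hi = max(0, j - half), min(vals.size, j + half + 1)
        else:
            lo, hi = max(0, j - window + 1), j + 1
        out[idx[j]] = vals[lo:hi].mean()
    return out


def normalize_per_capita(counts, population) -> np.ndarray:
    """Counts per 100,000 persons: ``counts_t / population_t * 1e5``."""
    c = np.asarray(counts, dtype=float)
    pop = np.asarray(population, dtype=float)
    if c.shape != pop.shape:
        raise ValueError("counts and population must have equal length")
    if np.any(pop <= 0):
        raise ValueError("population must be positive everywhere")
    return c / pop * 1e5


def to_normalized(
    series: MonthlySeries, window: int = 13, mode: str = "centered"
) -> NormalizedSeries:
    """Smooth, normalise per 100k, and re-index from the onset month.

    The default window of 13 months is the shortest odd span covering a
    full seasonal (and safety-net) cycle.

    Raises
    ------
    EmptySeriesError
        If the series has no non-zero count.
    """
    nz = np.flatnonzero(series.counts != 0)
    if nz.size == 0:
        raise EmptySeriesError(f"{series.drug_id}: series contains no prescriptions")
    smoothed = smooth_nonzero(series.counts, window, mode=mode)
    values = normalize_per_capita(smoothed, series.population)
    i0 = int(nz[0])
    return NormalizedSeries(
        drug_id=series.drug_id,
        t0_month=series.start_month + i0,
        values=values[i0:],
        window=window,
        left_censored=(i0 == 0),
    )


def monthly_population(population: pd.Series, months: pd.PeriodIndex) -> np.ndarray:
    """Align a population series to monthly resolution.

    ``population`` is indexed either by monthly ``Period`` (used directly)
    or by integer year, in which case each yearly figure is anchored at
    January and linearly interpolated between years (extrapolated flat at
    the ends).
    """
    idx = population.index
    if isinstance(idx, pd.PeriodIndex) and idx.freqstr.startswith("M"):
        aligned = population.reindex(months)
        if aligned.isna().any():
            missing = months[aligned.isna()]
            raise ValueError(f"population does not cover months: {list(missing[:3])}...")
        return aligned.to_numpy(dtype=float)
    years = np.asarray(idx, dtype=int)
    anchors = pd.PeriodIndex([pd.Period(f"{y}-01", freq="M") for y in years])
    x = anchors.astype(int).to_numpy(dtype=float)
    xq = months.astype(int).to_numpy(dtype=float)
    return np.interp(xq, x, population.to_numpy(dtype=float))
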