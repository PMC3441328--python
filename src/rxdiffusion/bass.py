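"""Closed-form Bass diffusion curves and derived adoption statistics.

The Bass model describes the uptake of an innovation by a population of
potential adopters.  The hazard of adoption at time ``t`` is ``p + q*F(t)``,
where ``F(t)`` is the fraction already adopted, ``p`` is the coefficient of
innovation (external influence: regulation, subsidy listing, marketing) and
``q`` the coefficient of imitation (internal influence: social contagion
among prescribers).  Solving ``dF/dt = (p + q*F)(1 - F)`` with ``F(0) = 0``
gives the cumulative adoption curve

    F(t) = (1 - exp(-(p+q) t)) / (1 + (q/p) exp(-(p+q) t))

Applied to prescribing, ``F`` is interpreted as the fraction of the eventual
(saturation) monthly prescription volume, so the observed per-capita monthly
volume is modelled as ``m * F(t)`` with ``m`` the saturation level in
prescriptions per 100,000 population per month.

All rates are per month; times are in months unless a function says
otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "BassParameters",
    "AdoptionSummary",
    "bass_cumulative",
    "bass_adoption_rate",
    "adoption_time",
    "peak_time",
    "adjusted_r2",
    "classify_adoption",
    "EXTERNAL_DOMINANT",
    "INTERNAL_DOMINANT",
]

EXTERNAL_DOMINANT = "external_dominant"
INTERNAL_DOMINANT = "internal_dominant"


def _validate_pq(p: float, q: float) -> None:
    if not p > 0:
        raise ValueError(f"p must be positive, got {p}")
    if q < 0:
        raise ValueError(f"q must be non-negative, got {q}")


@dataclass(frozen=True)
class BassParameters:
    """Fitted or true Bass parameters.

    Attributes
    ----------
    p : float
        Coefficient of innovation (external force), per month; > 0.
    q : float
        Coefficient of imitation (internal force), per month; >= 0.
    m : float
        Saturation level, prescriptions per 100,000 population per month.
    """

    p: float
    q: float
    m: float

    def __post_init__(self) -> None:
        _validate_pq(self.p, self.q)
        if not self.m > 0:
            raise ValueError(f"m must be positive, got {self.m}")

    @property
    def pq_ratio(self) -> float:
        """p/q from the raw values; +inf when q == 0."""
        if self.q == 0:
            return math.inf
        return self.p / self.q

    @property
    def classification(self) -> str:
        return classify_adoption(self.p, self.q)


@dataclass(frozen=True)
class AdoptionSummary:
    """Time scales of a fitted adoption curve.

    ``adoption_time_months`` is the time from the first recorded
    prescription until the modelled curve reaches ``saturation_fraction``
    of the saturation level; ``peak_time_months`` is the time of maximum
    adoption rate (0 whenever q <= p).
    """

    saturation_fraction: float
    adoption_time_months: float
    adoption_time_years: float
    peak_time_months: float


def bass_cumulative(p: float, q: float, t):
    """Cumulative adopted fraction F(t) of the Bass model.

    Parameters
    ----------
    p, q : float
        Innovation and imitation coefficients, per month.
    t : float or array_like
        Time in months since adoption onset; must be >= 0.

    Returns
    -------
    float or ndarray
        F(t) in [0, 1).  ``q = 0`` reduces to the pure exponential
        ``1 - exp(-p t)``.
    """
    _validate_pq(p, q)
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    e = np.exp(-(p + q) * t)
    out = (1.0 - e) / (1.0 + (q / p) * e)
    return out if out.ndim else float(out)


def bass_adoption_rate(p: float, q: float, t):
    """Instantaneous adoption rate f(t) = (p + q F(t)) (1 - F(t)).

    The rate integrates to 1 over [0, inf); its maximum sits at
    ``ln(q/p)/(p+q)`` when q > p and at t = 0 otherwise.
    """
    F = bass_cumulative(p, q, t)
    return (p + q * F) * (1.0 - F)


def adoption_time(p: float, q: float, f: float = 0.95) -> float:
    """Months until the cumulative curve reaches fraction ``f`` of saturation.

    Inverts ``bass_cumulative`` in closed form:

        t_f = ln((1 + f q/p) / (1 - f)) / (p + q)

    Parameters
    ----------
    f : float
        Target fraction of saturation, in (0, 1).  The study convention for
        "adopted" is f = 0.95, chosen to represent near-saturation since the
        model only asymptotes at the maximum.
    """
    _validate_pq(p, q)
    if not 0.0 < f < 1.0:
        raise ValueError(f"f must be in (0, 1), got {f}")
    return math.log((1.0 + f * q / p) / (1.0 - f)) / (p + q)


def peak_time(p: float, q: float) -> float:
    """Time of maximum adoption rate: ln(q/p)/(p+q) if q > p, else 0."""
    _validate_pq(p, q)
    if q > p:
        return math.log(q / p) / (p + q)
    return 0.0


def adjusted_r2(observed, predicted, k: int = 3) -> float:
    """Coefficient of determination adjusted for ``k`` fitted parameters.

    Returns ``1 - (1 - R^2) (n - 1)/(n - k - 1)`` with
    ``R^2 = 1 - RSS/TSS`` and TSS taken about the observed mean.

    Raises
    ------
    ValueError
        If the series lengths differ, ``n < k + 2``, or the observed series
        is constant (zero total sum of squares).
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError("observed and predicted must have equal length")
    n = obs.size
    if n < k + 2:
        raise ValueError(f"need at least k + 2 = {k + 2} observations, got {n}")
    tss = float(np.sum((obs - obs.mean()) ** 2))
    if tss == 0.0:
        raise ValueError("observed series is constant; R^2 is undefined")
    rss = float(np.sum((obs - pred) ** 2))
    r2 = 1.0 - rss / tss
    return 1.0 - (1.0 - r2) * (n - 1) / (n - k - 1)


def classify_adoption(p: float, q: float) -> str:
    """Classify an adoption as external- or internal-dominant.

    External-dominant iff p > q.  Ties (p == q, "evenly distributed"
    forces) are pooled with the internal-dominant class.
    """
    _validate_pq(p, q)
    return EXTERNAL_DOMINANT if p > q else INTERNAL_DOMINANT
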