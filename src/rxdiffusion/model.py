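"""Nonlinear least-squares fitting of the Bass model to adoption series.

The entry point is :class:`BassDiffusionModel`, built from a smoothed
per-100k prescription series (t = 0 at the first recorded prescription).
``fit()`` minimises

    sum_t ( y_t - m * F(t; p, q) )^2

over (p, q, m) and returns a :class:`BassDiffusionResults` carrying the
estimates, goodness of fit, the external/internal classification and the
derived adoption-time statistics.

Bass least squares is sensitive to initialisation and routinely drives q
to a boundary on near-exponential uptake curves, so the optimiser works in
log-parameters (guaranteeing positivity and taming p/q ratios spanning
many orders of magnitude) and restarts from a small grid of initial
values, keeping the best residual sum of squares.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .bass import (
    AdoptionSummary,
    BassParameters,
    adjusted_r2,
    adoption_time,
    bass_cumulative,
    classify_adoption,
    peak_time,
)
from .preprocess import EmptySeriesError, NormalizedSeries

__all__ = ["FitConfig", "FitResult", "BassDiffusionModel", "BassDiffusionResults", "fit_bass"]

_MIN_OBS = 12


@dataclass(frozen=True)
class FitConfig:
    """Optimiser settings for the Bass least-squares fit.

    ``p_starts``/``q_starts`` define the multi-start grid (the initial m is
    always the observed maximum).  ``q_floor`` is the lower optimisation
    bound for q: boundary fits with q -> 0 are genuine outcomes (pure
    external adoption), not failures.  ``saturation_fraction`` sets the
    adoption-time convention.
    """

    p_starts: tuple[float, ...] = (1e-3, 1e-2, 1e-1)
    q_starts: tuple[float, ...] = (1e-3, 1e-2, 1e-1)
    p_bounds: tuple[float, float] = (1e-8, 5.0)
    q_floor: float = 1e-12
    q_max: float = 5.0
    m_bounds_rel: tuple[float, float] = (1e-3, 1e3)
    saturation_fraction: float = 0.95
    ftol: float = 1e-10
    max_nfev: int = 10_000


@dataclass(frozen=True)
class FitResult:
    """Plain record of one fitted drug (the Results object distilled)."""

    params: BassParameters
    r2: float
    adjusted_r2: float
    rss: float
    n_obs: int
    converged: bool
    n_starts: int
    classification: str


class BassDiffusionModel:
    """Bass diffusion model of one drug's adoption series.

    Parameters
    ----------
    endog : array_like
        Smoothed prescriptions per 100,000 population per month, with
        index t = 0 at the first recorded prescription.
    t : array_like, optional
        Months since onset; defaults to ``0, 1, ..., len(endog) - 1``.
    drug_id : str, optional
        Label carried through to the results.

    Use :meth:`from_series` to build directly from a
    :class:`~rxdiffusion.preprocess.NormalizedSeries`.
    """

    def __init__(self, endog, t=None, drug_id: str = ""):
        self.endog = np.asarray(endog, dtype=float)
        if self.endog.ndim != 1 or self.endog.size == 0:
            raise ValueError("endog must be a non-empty 1-d sequence")
        if np.any(self.endog < 0):
            raise ValueError("endog must be non-negative")
        if not np.any(self.endog > 0):
            raise EmptySeriesError("series is identically zero; nothing to fit")
        self.t = (
            np.arange(self.endog.size, dtype=float)
            if t is None
            else np.asarray(t, dtype=float)
        )
        if self.t.shape != self.endog.shape:
            raise ValueError("t and endog must have equal length")
        self.drug_id = drug_id
        self.nobs = self.endog.size
        if self.nobs < _MIN_OBS:
            raise ValueError(
                f"need at least {_MIN_OBS} observations to fit, got {self.nobs}"
            )

    @classmethod
    def from_series(cls, series: NormalizedSeries) -> "BassDiffusionModel":
        # the series' own grid starts at t = 1: the first recorded month's
        # volume reflects one full month of accrual since onset
        return cls(series.values, t=series.t, drug_id=series.drug_id)

    def predict(self, params: BassParameters, t=None) -> np.ndarray:
        """Model mean m * F(t) at the given (or the fitted) months."""
        tt = self.t if t is None else np.asarray(t, dtype=float)
        return params.m * bass_cumulative(params.p, params.q, tt)

    def _residuals(self, theta: np.ndarray) -> np.ndarray:
        p, q, m = np.exp(theta)
        return self.endog - m * bass_cumulative(p, q, self.t)

    def fit(self, config: FitConfig | None = None) -> "BassDiffusionResults":
        """Multi-start nonlinear least squares over (log p, log q, log m).

        The best start by residual sum of squares wins; near-ties go to the
        smaller q.  If no start converges the best attempt is still
        returned, flagged ``converged=False``.
        """
        cfg = config or FitConfig()
        ymax = float(self.endog.max())
        lb = np.log([cfg.p_bounds[0], cfg.q_floor, cfg.m_bounds_rel[0] * ymax])
        ub = np.log([cfg.p_bounds[1], cfg.q_max, cfg.m_bounds_rel[1] * ymax])

        best = None  # (rss, q, theta, success)
        n_starts = 0
        for p0, q0 in itertools.product(cfg.p_starts, cfg.q_starts):
            n_starts += 1
            theta0 = np.clip(np.log([p0, q0, ymax]), lb, ub)
            try:
                # ill-conditioned trust-region steps are expected far from
                # the optimum; silence the transient numpy warnings
                with np.errstate(all="ignore"):
                    sol = least_squares(
                        self._residuals,
                        theta0,
                        bounds=(lb, ub),
                        ftol=cfg.ftol,
                        xtol=None,
                        gtol=None,
                        max_nfev=cfg.max_nfev,
                        method="trf",
                    )
            except Exception:
                continue
            rss = float(2.0 * sol.cost)
            qhat = float(np.exp(sol.x[1]))
            cand = (rss, qhat, sol.x, bool(sol.success))
            if best is None:
                best = cand
            else:
                # near-ties in RSS broken toward the smaller q
                if rss < best[0] * (1 - 1e-9):
                    best = cand
                elif abs(rss - best[0]) <= 1e-9 * max(best[0], 1e-300) and qhat < best[1]:
                    best = cand
        if best is None:
            raise RuntimeError("all optimizer starts raised; series is unfittable")

        rss, _, theta, success = best
        p, q, m = (float(v) for v in np.exp(theta))
        params = BassParameters(p=p, q=q, m=m)
        fitted = self.predict(params)
        tss = float(np.sum((self.endog - self.endog.mean()) ** 2))
        r2 = 1.0 - rss / tss if tss > 0 else float("nan")
        try:
            adj = adjusted_r2(self.endog, fitted, k=3)
        except ValueError:
            adj = float("nan")
        return BassDiffusionResults(
            model=self,
            params=params,
            rss=rss,
            r2=r2,
            adj_r2=adj,
            converged=success,
            n_starts=n_starts,
            config=cfg,
        )


class BassDiffusionResults:
    """Estimates and diagnostics from a Bass model fit.

    Attributes
    ----------
    params : BassParameters
        Point estimates (p, q, m).
    pq_ratio : float
        p/q from the raw estimates (+inf when q hits zero).
    classification : str
        ``external_dominant`` iff p > q, else ``internal_dominant``.
    rsquared, rsquared_adj : float
        Plain and adjusted coefficients of determination (k = 3).
    """

    def __init__(self, model, params, rss, r2, adj_r2, converged, n_starts, config):
        self.model = model
        self.params = params
        self.rss = rss
        self.rsquared = r2
        self.rsquared_adj = adj_r2
        self.converged = converged
        self.n_starts = n_starts
        self.config = config
        self.nobs = model.nobs

    @property
    def pq_ratio(self) -> float:
        return self.params.pq_ratio

    @property
    def classification(self) -> str:
        return classify_adoption(self.params.p, self.params.q)

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.model.predict(self.params)

    @property
    def resid(self) -> np.ndarray:
        return self.model.endog - self.fittedvalues

    def predict(self, t=None) -> np.ndarray:
        return self.model.predict(self.params, t=t)

    def adoption_summary(self, f: float | None = None) -> AdoptionSummary:
        """Adoption time to fraction ``f`` of saturation (default from config)."""
        frac = self.config.saturation_fraction if f is None else f
        months = adoption_time(self.params.p, self.params.q, frac)
        return AdoptionSummary(
            saturation_fraction=frac,
            adoption_time_months=months,
            adoption_time_years=months / 12.0,
            peak_time_months=peak_time(self.params.p, self.params.q),
        )

    def to_record(self) -> FitResult:
        return FitResult(
            params=self.params,
            r2=self.rsquared,
            adjusted_r2=self.rsquared_adj,
            rss=self.rss,
            n_obs=self.nobs,
            converged=self.converged,
            n_starts=self.n_starts,
            classification=self.classification,
        )

    def summary(self) -> str:
        """Human-readable fit summary."""
        s = self.adoption_summary()
        lines = [
            "Bass Diffusion Model Results",
            "=" * 46,
            f"{'Drug:':<28}{self.model.drug_id or '<unnamed>'}",
            f"{'No. observations (months):':<28}{self.nobs}",
            f"{'Converged:':<28}{self.converged} ({self.n_starts} starts)",
            "-" * 46,
            f"{'p (external, /month):':<28}{self.params.p:.6g}",
            f"{'q (internal, /month):':<28}{self.params.q:.6g}",
            f"{'m (per 100k /month):':<28}{self.params.m:.6g}",
            f"{'p/q ratio:':<28}{self.pq_ratio:.3e}",
            f"{'Classification:':<28}{self.classification}",
            "-" * 46,
            f"{'R-squared:':<28}{self.rsquared:.4f}",
            f"{'Adj. R-squared:':<28}{self.rsquared_adj:.4f}",
            f"{'RSS:':<28}{self.rss:.6g}",
            "-" * 46,
            f"Adoption time to {s.saturation_fraction:.0%} of saturation: "
            f"{s.adoption_time_months:.1f} months ({s.adoption_time_years:.2f} years)",
            f"{'Peak adoption rate at:':<28}{s.peak_time_months:.1f} months",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Observed series and fitted adoption curve (matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4))
        ax.plot(self.model.t, self.model.endog, lw=1, color="C0", label="observed")
        ax.plot(self.model.t, self.fittedvalues, lw=2, color="k", label="Bass fit")
        s = self.adoption_summary()
        ax.axvline(s.adoption_time_months, color="C3", ls="--", lw=1,
                   label=f"{s.saturation_fraction:.0%} of saturation")
        ax.set_xlabel("months since first prescription")
        ax.set_ylabel("prescriptions per 100,000 per month")
        if self.model.drug_id:
            ax.set_title(self.model.drug_id)
        ax.legend(frameon=False)
        return ax


def fit_bass(series: NormalizedSeries, config: FitConfig | None = None) -> BassDiffusionResults:
    """Fit the Bass model to a preprocessed series (convenience wrapper)."""
    return BassDiffusionModel.from_series(series).fit(config)
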