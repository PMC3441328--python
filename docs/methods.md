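# Methods

## Model

A drug's smoothed monthly prescription volume per 100,000 population is
modelled as `y_t = m F(t) + e_t`, where `F` is the cumulative Bass
diffusion curve

    F(t) = (1 - exp(-(p+q)t)) / (1 + (q/p) exp(-(p+q)t)),

the solution of `dF/dt = (p + qF)(1 - F)`, `F(0) = 0`. Interpreting `F`
as the fraction of the eventual monthly volume assumes the drug's market
potential is fixed over the observation window and that the per-capita
normalisation removes demand growth; competition within a therapeutic
class, formulary changes mid-series and evidence reversals are not
modelled. The classification rule — external-dominant iff `p > q`,
with exact ties pooled into the internal class — describes which force
dominates the fitted uptake, not a causal decomposition.

### Time origin

Monthly data are aggregates: the volume recorded for a month reflects the
adoption accrued by the *end* of that month. Adoption is therefore taken
to start at the beginning of the first recorded prescription month, and a
series trimmed to start at that month is fitted on the grid `t = 1..n`
(one month of accrual for the first observation). Without this
convention, fitting `m F(t)` on `t = 0..n-1` to a series whose first
value is non-zero misattributes the first month's volume and biases `p`
upward by several percent even on noise-free data. Arrays passed directly
to `BassDiffusionModel` (for example, curves that genuinely begin at
zero) default to `t = 0..n-1`. Adoption times are measured from the
adoption origin `t = 0`.

## Estimation

`(p, q, m)` minimise the residual sum of squares via `scipy`'s
trust-region-reflective least squares, parameterised as
`(log p, log q, log m)`. The log parameterisation enforces positivity and
tames the dynamic range of `p/q` — published fits span ratios from 1e-3
to ~1e11, i.e. `q` is sometimes driven to an effective zero, so the lower
optimisation bound for `q` is 1e-12 per month and boundary fits are
treated as genuine outcomes. Bass least squares is initialisation-
sensitive; the fit restarts from the 3x3 grid
`p0, q0 in {1e-3, 1e-2, 1e-1}` with `m0 = max(y)`, keeps the best RSS and
breaks near-ties (relative difference <= 1e-9) toward the smaller `q`.
Convergence uses `ftol = 1e-10` with at most 10,000 function evaluations
per start; if no start converges, the best attempt is returned flagged
`converged=False` rather than raising. Fits require at least 12 monthly
observations. Goodness of fit is reported as plain and adjusted R-squared
(`k = 3` fitted parameters); adjusted is the default in summaries.
The default adoption-time convention is `f = 0.95` of saturation, with
`f` configurable (e.g. 0.90).

## Preprocessing

Raw volumes are smoothed with a moving average taken *over the non-zero
values*: the non-zero entries are compacted, averaged with a centred
window truncating at the ends, and scattered back; zero months never
enter an average and stay zero. The window is 13 months — the smallest
odd span covering a full seasonal and safety-net cycle (the window length
is not stated in the source analysis; a trailing variant is available).
Counts are then converted to prescriptions per 100,000 using the monthly
national population, linearly interpolated when only annual figures are
supplied, and the series is trimmed to start at the first non-zero month.
Drugs already prescribed in the first observed month are flagged
left-censored. Smoothing distorts genuinely fast uptakes (saturation
within ~2 years): the moving average smears the rise and can bias `q`
downward by tens of percent there, while leaving the derived adoption
time far more stable. For fast adopters a shorter window is advisable.

## Synthetic cohorts

The generator emulates the study corpus the pipeline was designed for:
103 drugs over 216 months, a starting population of 17.5 million growing
1.2% per year, onsets uniform over the first 120 months, `p` and `q`
log-uniform on [1e-3, 0.3] per month oriented so that ~19/103 of drugs
are external-dominant, and saturation levels log-uniform on [10, 3000]
per 100k per month. The expected count at month `t >= onset` is
`m F(t - onset + 1) * population_t / 1e5 * s_t`, where `s_t` is a
multiplicative sinusoidal seasonal factor (amplitude 0.10) times a 1.25
December safety-net spike; observed counts are Poisson (default) or
gamma-mixed negative binomial draws. The seasonal amplitudes are
plausible placeholders, exposed in the config, not estimates. Per-drug
random substreams derive from `(seed, drug index)`, so a drug's series is
independent of cohort size and every run is reproducible from one seed.

What the simulations do *not* contain: market competition between drugs,
prescriber-level heterogeneity or networks, policy shocks mid-series,
partial-year listing effects, or measurement artefacts beyond counting
noise. Passing recovery tests therefore shows the pipeline is internally
consistent under the stated noise model, not that real prescription
series satisfy the Bass assumptions.

## Cohort statistics

Medians and quartiles use linear interpolation between order statistics
(the quantile convention of the source summaries is unknown; reproduction
tolerances absorb the difference). Group comparisons use the
Kruskal-Wallis H test on mid-ranks with the tie-correction divisor
`1 - sum(t^3 - t)/(N^3 - N)`; p-values come from the chi-square upper
tail with `k - 1` degrees of freedom (adequate at the group sizes in
scope; no exact small-sample tables). Because published adoption times
carry ties at 2-decimal precision, summaries report the comparison both
with and without tie correction. A degenerate all-tied input returns
`H = 0, p = 1` by convention rather than 0/0. Sub-group comparisons drop
groups below a configurable minimum size (default 4).

## Packaged reference table

`data/table1.csv` transcribes a published per-drug table of 103 adoptions
(drug, anatomical main group, first subsidised month, maximum monthly
per-100k volume, p/q ratio, R², adoption time in years, and an
external-dominant flag). The transcription is validated at load time
(103 rows; the flag must equal `p/q > 1`, 19 rows). Summaries recomputed
from it reproduce the published cohort statistics to within rounding of
the 2-decimal table values: median adoption time 8.25 years (IQR
4.96-12.04), median R² 0.974 (IQR 0.949-0.9875), and a two-group
Kruskal-Wallis p of 0.0205 for shorter adoption times in the
internal-dominant class.

## Problem sizes in the validation suite

The recovery experiments use one 103-drug cohort at default settings for
the end-to-end rank-correlation and classification checks, 50 Poisson
replicates of a single 180-month drug (`p = 0.005, q = 0.06, m = 2000`)
for the `q`-recovery study, and a 6x6 `(p, q)` grid against a numerical
ODE oracle for the closed forms. These sizes give stable medians and
correlations while keeping the whole suite fast.

## Known limitations

- Estimates for drugs still far from saturation at the end of the window
  are extrapolations and less reliable however good the fit.
- `m` is fitted freely; if the true series has not plateaued, `m` and the
  adoption time are jointly under-identified.
- The chi-square approximation for Kruskal-Wallis is poor below ~5
  observations per group; the packaged comparisons are far from that
  regime.
- Left-censored drugs (first prescription in the first observed month)
  have unknown true onsets; they are flagged, not corrected.
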