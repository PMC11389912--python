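# Methods

`strokecast` implements a forecasting pipeline for days with extremely
high daily ischemic-stroke counts, driven by meteorological time series.
This note documents the statistical procedures, the numerical choices
behind them, and what the synthetic validation does and does not show.

## The extreme-day series

A daily count series `y_t` is transformed into a binary series `Ext_t`:

1. **Smoothing.** `s_t = Σ_{i=0..6} y_{t−i}`, a trailing 7-day rolling
   sum. Trailing windows mean the value at day t uses days ≤ t only; any
   missing count inside the window makes the sum missing (a registry gap
   should not silently deflate the weekly load).
2. **Detrending.** A cubic smoothing-spline trend is removed:
   `r_t = s_t − f̂(t)`. The spline is a penalized cubic regression spline
   (B-spline basis over K equally spaced knots, exact curvature penalty
   `λ∫f''²`), with λ chosen by generalized cross-validation. K follows an
   n-dependent rule (≈118 at n=500, ≈160 at n=1800, capped near 200) in
   the tradition of classical smoothing-spline software; keeping K ≪ n
   both speeds up the fit (the GCV curve comes from one K×K
   eigendecomposition) and limits how much serial noise the trend can
   absorb. We verified on identical data that this construction selects
   essentially the same effective degrees of freedom as R's
   `smooth.spline` (both ≈138 on a 794-day rolling-sum series).
3. **Dynamic binarization.** `Ext_t = 1` iff `r_t` strictly exceeds the
   90th percentile (linear interpolation between order statistics) of
   `{r_u : u < t}`, computed over all past days once at least
   `min_history = 100` of them are available. "Strictly exceeds" means
   ties fall to 0; the current value never informs its own threshold.
   Days before the rolling warm-up (6) plus `min_history` are missing.

A non-adaptive alternative (`binarize_fixed_first_n`) thresholds at the
90th percentile of the first 500 values; it is provided for comparison
but cannot adapt to level drift.

With a 90th-percentile rule the design extreme rate is 10%; on
exchangeable input the realized post-warm-up rate is 0.10 ± 0.02 at
n = 2000 (tested). On rolling-sum residuals it is close but not exact,
because the residuals are autocorrelated and the threshold adapts.

## Why the sequential study uses a retrospectively built extreme series

The forecasting study (below) needs `Ext_t` as ground truth at every
origin t. Two constructions are implemented:

* `ext_mode="retrospective"` (default): `Ext` is built **once** from the
  full count series; the sequential discipline applies to model fitting
  and to the lagged predictors (only days ≤ t−1 enter either).
* `ext_mode="sequential"`: the entire construction — rolling sum, spline,
  running percentile — is re-run on the counts truncated at each origin,
  so even the spline never sees the future.

The literal sequential variant turns out to be statistically degenerate:
a smoothing spline has high leverage at its right boundary, so the
residual of the newest day is shrunk toward zero, and the newest day
almost never exceeds the percentile of (un-shrunk) interior residuals.
Empirically the ground-truth extreme rate drops from ≈10% to ≈1–2% and
the persistence-based forecaster's AUC falls far below chance — an
artifact of boundary leverage, not a property of the data. We verified
the same boundary behavior with R's `smooth.spline` on identical input.
The retrospective default trades a small, smooth-trend-only leakage into
the *definition of the target* (not into any predictor or fit) for a
well-defined target with the intended 10% base rate. The sequential
variant is retained for sensitivity analyses.

## The lagged design

The model for `Ext_t` uses, as predictors: `Ext_{t−1..t−3}`; eleven
meteorological variables (t_max, t_min, t_ampl, t_mean, pressure,
humidity, wind, precipitation, WCI, DI, ETV) each at lags 1–3; and
calendar terms — day-of-week (categorical, 6 dummies), ISO week-of-year
(numeric), month (categorical, 11 dummies), year (categorical).
Categoricals are treatment-coded against the first level. By default the
meteorological series are first smoothed with a trailing 7-day rolling
mean, consistent with the smoothed-series correlation screening; raw
daily values are a switch away. Rows with any missing predictor or
response are dropped and counted.

Because `t_ampl = t_max − t_min` holds exactly, each lagged amplitude
column is linearly aliased with the corresponding min/max pair. Fitters
guard against this with pivoted-QR aliasing detection and drop a minimal
set of dependent columns (as R's `glm` drops aliased coefficients);
predictions are invariant to which representative survives.

## Forecasters

**Logistic regression** is fit by iteratively reweighted least squares
with a deviance-change tolerance of 1e−8 (max 100 iterations), using a
rank-revealing least-squares step so near-aliasing stays stable.
Complete separation is detected (every case classified perfectly with
diverging linear predictor) and flagged, not raised — the fitted
probabilities remain usable as scores. Quasi-separated calendar cells
(a level containing no extreme days) have their MLE at infinity; the
early-stopped coefficient yields a score ≈ 0 for such cells, which is
the sensible forecast. McFadden's pseudo-R² is `1 − ℓ/ℓ₀` with `ℓ₀`
from the closed-form intercept-only fit; AIC = −2ℓ + 2k and
BIC = −2ℓ + k·log n count k over non-aliased columns.

**Backward AIC elimination** removes whole terms (a categorical's dummy
block moves as a unit), at each step dropping the term whose removal
lowers AIC most, until no removal helps. Note the calibration this
implies: a pure-noise term survives when its likelihood-ratio statistic
exceeds 2, which happens with probability P(χ²₁ > 2) ≈ 0.157 — AIC
selection is not a consistency guarantee, and tests assert accordingly.

**Random forest** is a 500-tree classification forest on the same design
(`max_features="sqrt"`, scikit-learn defaults otherwise), scored by the
forest's class-1 probability. Importances are reported both as Gini
impurity decrease and as permutation importance (mean accuracy drop over
5 shuffles, on the training sample). An optional moving-block bootstrap
(default block length 10 days) replaces the per-observation resample to
preserve short-range serial dependence within each tree's sample; the
standard bootstrap is the default.

**Croston's method** treats the binary extreme series as intermittent
demand: exponentially smoothed nonzero size `z̃` and inter-event interval
`p̃` (both with α = 0.5, balancing recent and past values), forecast
`z̃/p̃`. Initialization uses the first nonzero observation and its
1-based position; before any event the forecast is 0 by convention. The
classic (not bias-corrected) form is used. For binary input the forecast
lies in [0, 1].

## The sequential study

Forecasting starts at day 500 (1-based from the series start) and walks
one day at a time to the end. At origin t the GLM is refit on all
complete design rows with target ≤ t−1 (daily, cold-started — see the
separation note above for why warm-starting across days would make
scores irreproducible), the forest is refit every 7 days (its fits
dominate the runtime; the information gained per day is tiny, and the
AUC difference between daily and monthly GLM refits on null data is
< 0.05, tested), and Croston's recursion is advanced along the extreme
history. Every origin is logged — a day where a model cannot score
(e.g. a single-class training response) is recorded as missing, never
dropped. Forest refits are seeded deterministically from (seed, origin).

## Evaluation

* **AUC** by the Mann–Whitney formulation (ties count ½); it equals the
  trapezoidal area under the empirical ROC (tested to 1e−12).
* **Youden point**: thresholds are midpoints between adjacent distinct
  scores plus ∓∞ sentinels, a day is called positive when its score is
  strictly above the threshold, and among maximizers of
  sensitivity + specificity − 1 the smallest threshold wins — in a
  surge-warning setting the costly error is the missed surge.
* **Paired bootstrap AUC test**: days are resampled with replacement,
  stratified by class (so both classes survive in every replicate),
  jointly for both methods' scores and the shared truth; B = 2000; the
  two-sided p-value is `2·min(P(Δ≤0), P(Δ≥0))` with the add-one
  correction `(count+1)/(B+1)`, capped at 1.
* **Benjamini–Hochberg** step-up adjustment across the three pairwise
  comparisons.
* **Cross-correlation screen**: `ccf(x, y)` at lag k correlates the
  outcome at t+k with the exposure at t (positive lags: exposure leads),
  normalized by full-series standard deviations with divisor n, with the
  ±1.96/√n strict-white-noise band. Outcome series are used as given;
  exposure series are 7-day rolling means by default.

## Synthetic data

The generator emulates the statistical shape of a mid-European district
registry over five years: Poisson daily counts with mean 2.6 (≈7.4%
zero days; a negative-binomial option with size θ adds the mild
overdispersion registries often show), optional log-scale annual/weekly
seasonality and trend (all default 0), and meteorological series that
are an annual cosine plus stationary AR(1) noise per variable (t_mean:
10 ± 10 °C annual swing, AR 0.8, sd 2.5 °C; humidity ~75%; water-vapour
pressure ~12 hPa; wind ~3.5 m/s; zero-inflated exponential
precipitation). Daily extremes are t_mean ± independent positive
half-ranges, so `t_ampl = t_max − t_min` holds exactly. The three
comfort indices use standard published forms — Siple–Passel wind chill,
Thom's discomfort index, Missenard's effective temperature with wind —
and are overridable callables, since operational services use local
variants. Planted effects enter the log intensity per standard
deviation of the (lagged) variable, so coefficients are comparable
across variables; the default is none, matching the negligible-
association regime the pipeline is designed to detect.

What the generator does **not** emulate: spatial structure across
districts, weather fronts (beyond AR(1) persistence), holiday effects,
reporting artifacts, or genuine meteorological causation unless planted.
Passing tests therefore show the *machinery* is calibrated and powerful
enough to detect a planted lag-1 effect of 1.0 SD — not that real stroke
counts behave like the generator.

## Numerical choices

* Spline: ridge `1e−8·mean(diag(BᵀB))` stabilizes the Cholesky when the
  basis is near-degenerate (e.g. long interior gaps); GCV's λ is found
  by golden-section search on log₁₀λ ∈ [−4, 12].
* Logistic: linear predictors clipped at ±35 before the sigmoid;
  probabilities clipped at 1e−12 inside log-likelihoods; IRLS weights
  floored at 1e−10.
* Quantiles: linear interpolation between order statistics throughout.
* Bootstrap and forest seeds derive deterministically from the run seed.
* Croston: zero observations leave the smoothed estimates untouched
  (only the interval counter advances), per the classic recursion.

## Problem sizes used in validation

Tests run the full sequential study at n = 1500 days (≈1000 forecast
origins) for the null-data envelope with all three methods, and 20
replicates of n = 1500 with GLM and Croston for the planted-effect power
check; the acceptance script uses the full five-year span (n = 1826).
These sizes keep a complete validation run in the tens of minutes on a
single CPU while matching the study's scale.

## Known limitations

* The extreme definition is single-resolution and single-quantile; no
  multi-day-horizon forecasts.
* The retrospective target definition leaks the smooth trend (only)
  into the target's definition; see the dedicated section above.
* Backward-only AIC selection is order-sensitive in the presence of
  heavy collinearity; the reduced model's exact term set should not be
  over-interpreted (its fit statistics are stable, its membership is
  not).
* The dynamic threshold makes the binary series non-stationary early
  on, when the percentile is estimated from few residuals; `min_history`
  bounds but does not remove this.
* Re-running the construction on a longer history flips ≈11% of
  classifications of days near the cutoff (measured; see tests) — the
  binary series is a statistic of the whole history, not a fixed label.
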