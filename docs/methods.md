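# Methods

This note documents the models, conventions and numerical choices behind
`droughtfire`, in the order the pipeline runs them.

## SPEI

The climatic water balance of month *t* is `D(t) = P(t) − PET(t)` (mm).

**Thornthwaite PET.** `PET = 16 · K(lat, month) · (10 T / I)^a` for months
with mean temperature `T > 0` °C, and `PET = 0` for frozen months.  The
annual heat index `I = Σ (T̄_m / 5)^1.514` is computed from the
*climatological* monthly normals `T̄_m` of the supplied series (negative
normals contribute nothing); `a` is the standard cubic polynomial in `I`;
`K` is the day-length correction from solar declination at the mid-month day
of a 365-day calendar, times days-in-month/30.  The high-temperature
(> 26.5 °C) Thornthwaite variant is deliberately **not** used: the classical
formula applies at all `T > 0`.  A perennially frozen series returns PET ≡ 0
rather than an error.

**Accumulation.** `D_k(t) = Σ_{i=t−k+1..t} D(i)` for `k ∈ {1, 3, 6, 12}`.
The first `k−1` values are *missing*, never zero — zero is a meaningful
standardized value.

**Standardization.** Per calendar month, a three-parameter log-logistic
`F(x) = [1 + (α/(x−γ))^β]^{−1}` is fitted to the calibration values of `D_k`
by unbiased probability-weighted moments, and
`SPEI = Φ⁻¹(F(D_k))` via the Abramowitz–Stegun rational approximation
(constants 2.515517/0.802853/0.010328 and 1.432788/0.189269/0.001308), the
convention used throughout the SPEI literature.  Numerical guards:

* The PWM shape estimate is the reciprocal sample L-skewness, feasible only
  for right-skewed samples.  A left-skewed calendar month is fitted on the
  negated sample and evaluated as `F(x) = 1 − F₋(−x)` (flag `reflected`).
  This keeps the transform monotone and the standardization calibrated.
* If the fitted origin γ exceeds the sample minimum, it is clamped just below
  it (standard support guard).
* Fitted probabilities are clipped to `[1e−9, 1−1e−9]` before the quantile
  map, so far-out-of-calibration future values give large finite deviates.
* A constant or exactly symmetric calibration month is flagged (SPEI left
  missing there), not fatal.
* At least 20 defined calibration values per calendar month are required.

**Calibration window.** Default: each series is self-calibrated on its own
full span.  Future scenario series can instead be standardized against the
historical window (`calibration="historical"`), which concatenates the series
and restricts the fit window; both modes exist because the choice materially
changes the *meaning* of future SPEI (anomalies w.r.t. the future's own
climate vs. the historical climate) and neither is asserted as canonical.

## Run-theory drought events

A drought event is a maximal run of consecutive months with
`SPEI ≤ threshold` lasting at least 3 months.  Conventions:

* The threshold itself counts as drought: the light-drought class is the
  half-open interval (−1.0, −0.5], so −0.5 belongs to it.  Exceedance
  semantics are used throughout — a run at threshold −0.5 continues while
  SPEI dips below −1.
* The end time is *exclusive* (first month after the run), so
  `DD = DTT − DIT` equals the month count exactly.
* Missing SPEI terminates a run: continuity cannot be certified across a gap.
* Period aggregates: `MDN = n/y` (events · yr⁻¹), `MDD/MDS/MDI` arithmetic
  means over events *assigned by their start month*; an event spanning a
  period boundary belongs wholly to the period containing its start and is
  not cut.  A zero-event cell gets 0 for all four aggregates (flagged
  `empty`) so the regression sees complete covariates; 0 sits at the
  "no drought" end of both sign conventions.

## Covariates

Terrain roughness is the elevation range within a cell; road/river density is
length over area.  All predictors entering the regression — the seven static
covariates *and* the retained principal components — are min–max scaled to
[0, 1] with extremes taken from the training sample; stored parameters are
reapplied to future data with clipping to [0, 1], keeping the logistic linear
predictor inside the trained domain (clipping, not extrapolation, is a
deliberate flag-documented choice; future PC scores use historical extrema).

The four drought characteristics are strongly collinear (duration and
severity near-perfectly, opposite in sign).  PCA on the correlation matrix
(standardize, then eigendecompose) replaces them: components are retained in
decreasing-variance order until cumulative variance ≥ 90 % (three, in
practice).  Eigenvector sign is arbitrary, so each loading column's
largest-magnitude entry is made positive — a fixed convention, documented
rather than matched to any external table.  The fitted means, SDs and
loadings are serialized to JSON and reused bit-exactly for future periods.
VIF uses the standard `1/(1−R²)` with an intercept in each auxiliary
regression; exact dependence reports `inf` rather than raising.

## Global and geographically weighted logistic regression

The response per cell is binomial: fire-years out of observed years (a
`binary` mode — fire ever/never — exists as a flag).  Fitting is
iteratively reweighted least squares with convergence at a maximum
coefficient change below 1e−8 or 100 iterations; complete separation is
flagged as non-convergence, not an exception.

The geographically weighted model refits at every calibration location with
observation weights from an adaptive bi-square kernel: the bandwidth of
location *i* is the great-circle distance (haversine, R = 6371 km) to its
N-th nearest point (itself included, so the diagonal weight is 1), and
`w = (1 − (d/b)²)²` inside the bandwidth, zero outside.  Numerical choices:

* A 1e−8 diagonal ridge is added when a local weighted design is
  near-singular (condition number > 1e12), flagged per location; if a local
  fit is still unusable the bandwidth is enlarged for that location until the
  problem is well posed.
* The model log-likelihood sums each observation's binomial contribution at
  its own location's fit.  The effective parameter count for AIC/AICc is the
  trace of the hat-like projection matrix of the final IRLS step
  (`x_iᵀ (XᵀV_iX)⁻¹ x_i · v_ii` summed over locations), the GWR4-style
  convention — the AICc formula leaves `k` open for local models, so the
  convention is documented rather than asserted.  The trace is capped at
  `m − 2` to keep AICc inside its domain.
* Bandwidth selection: golden-section search over integer neighbour counts
  on a unimodality assumption, endpoints always evaluated, deterministic
  tie-break to the smaller bandwidth, full trace returned; a `grid` method
  exists for non-unimodal profiles.  With all weights forced to one
  (`bandwidth=None`) every local fit equals the global fit — the suite's
  central correctness anchor.
* Prediction at a location outside the calibration set re-estimates local
  coefficients there by a kernel-weighted fit over the calibration data.

Regional coefficient summaries are arithmetic means of local coefficients
over the cells of each region.

## Evaluation

Observed FP is fire-years over period years, with records binned into
half-open cells `[west, east) × [south, north)` (a partition; no double
counting) and coordinate-free or out-of-grid records dropped with a count.
AUC comes from the Mann–Whitney U statistic with midrank ties
(`U/(n₁n₀)`), its significance from the normal approximation — the printed
"P < 0.001" style of test; DeLong intervals are out of scope.  Test labels
are binary (≥ 1 fire in the cell during the short test window).  If the test
window yields one-class labels, the report omits AUC with a reason instead of
failing.

## Projection

The ensemble average is taken on the *climate* fields first (per-cell
per-month mean of temperature and precipitation across members), and SPEI /
drought characteristics are computed on the ensemble-mean series; a
per-member-then-average mode is available for sensitivity checks.  Static
covariates are frozen at historical values; only the drought characteristics
change.  The historical reference for ΔFP is the **model-predicted**
historical probability (so the difference isolates the covariate change);
differencing against raw observed FP is available by flag.  Regional
summaries average ΔFP over cells with `forest_fraction ≥ 0.5` (default mask)
and are reported in percentage points.  Because future characteristics pass
through the stored PCA and normalization, feeding historical characteristics
back through the projection reproduces the fitted historical probabilities
bit-exactly — an identity the tests assert.

## Synthetic world

The generator produces the statistical structure the analysis assumes, not
any real geography:

* **Grid.** Square cells (default 0.5°) from a configurable origin (default
  100°E, 35°N — mid-latitude, so northern winters freeze and the
  Thornthwaite `T ≤ 0` branch is exercised), partitioned into up to seven
  contiguous rectangular region blocks as stand-ins for real reporting
  regions.
* **Climate.** Temperature = latitude baseline (16 °C at the southern edge,
  −1.2 °C per degree northward) + 14 °C seasonal cosine (July peak) + linear
  trend (°C/decade) + Gaussian noise (SD 1.5 °C).  Precipitation has gamma
  marginals (shape 2.2, seasonal monsoon-peaked mean 18–113 mm/month) driven
  through a latent-Gaussian quantile transform whose driver mixes an AR(1)
  wetness anomaly (coefficient 0.8, 70 % of driver variance) with white
  noise.  This is the standard stochastic-weather-generator construction: it
  gives realistic monthly skewness (~1.3) *and* the multi-month wet/dry
  spells run-theory needs.  An earlier multiplicative-lognormal design
  produced monthly skewness near 5 — unrealistic, and outside what PWM
  log-logistic standardization absorbs — and was replaced.  A positive
  trend also dries precipitation by 3 %/decade per unit trend, giving the
  monotone scenario ordering.
* **Truth.** The drought predictor's true coefficient flips sign at the
  domain midline via `−A·tanh(3·f)` with `f` the fractional latitude from
  the midline (amplitude default 3 on normalized predictors): a smooth
  two-regime surface, the analogue of fire-promoting drought in the south
  and fire-inhibiting drought in the north.  A linear profile is available
  (`profile="linear"`).  Other predictors get constant coefficients ~N(0,
  0.4).  Intercept −1 puts mean annual fire probability near 0.27.
* **Fires.** Each cell-year is a fire-year with its cell's probability;
  fire-years emit 1 + Poisson(0.5) point records uniform in the cell.
* **Seeding.** One master seed spawns independent streams (grid, climate,
  covariates, truth, fires) via SeedSequence spawn keys, so regenerating one
  product never perturbs another.

What a green synthetic test does *not* establish: realism of any absolute
probability level, spatial correlation of real fire ignitions (records are
conditionally independent given the cell probability), GCM-specific biases,
or the magnitudes of real regional probability changes — those depend on
restricted fire archives and large climate downloads that are out of scope.

## Scaled-down defaults

The shipped configuration runs a 12×12 grid, 20 + 2 historical years, and
30 future years split into two periods, with 3 ensemble members per scenario
— minutes of compute instead of the full 78-year, 15-member setup.  All the
full-scale windows (2022–2040 / 2041–2060 / 2080–2099, more members, larger
grids) are reachable through the config; nothing in the code is specific to
the reduced size.

## Known limitations

* Thornthwaite PET is temperature-only and known to misbehave in arid and
  high-latitude climates; a Penman–Monteith option is future work.
* The bandwidth search assumes a unimodal AICc profile (the grid fallback
  exists but is slower).
* The Mann–Whitney normal approximation is asymptotic; p-values at very
  small cell counts are indicative only.
* Exact numeric parity with external SPEI data products is not claimed: the
  fit here is a clean-room PWM implementation, and published products may
  use different fitting constants.
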