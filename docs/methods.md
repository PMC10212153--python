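# Methods

## Detection events

Camera traps fire repeatedly while an animal lingers, so the analysis unit is
the independent detection event: within one station × species stream, a
record opens a new event iff its gap to the *immediately preceding record*
strictly exceeds the threshold (30 min for wildlife, 1 min for humans —
recreationists traverse a trail camera's field of view far faster and far
more often than wildlife revisit it). The chain rule (gap to the previous
record, not to the event's first record) is standard camera-trap practice and
matches the usual "more than X minutes after another image" definition; an
`anchor="event_start"` variant exists for sensitivity analysis. A gap of
exactly the threshold does not split an event ("more than"). Humans are one
undifferentiated class.

## Nocturnality

For an event at local clock time `t` on date `d`,
`N = min(|t − noon(d)|, 24 − |t − noon(d)|)` in decimal hours, where
`noon(d)` is the solar transit computed from the NOAA Fourier-series equation
of time plus the longitude and UTC-offset corrections (validated against an
independent sun-right-ascension formulation to under a minute over
1950–2100). The circular wrap guarantees the codomain [0, 12] even when solar
noon sits far from clock noon. The reference transit is the one of the
event's own calendar date (not the nearest transit); the difference is at
most the ~0.3 min/day drift of transit time. Solar noon is evaluated at each
station's own coordinates by default; a single-reference-point mode exists.
Timestamps carry one fixed UTC offset for the whole study — no
daylight-saving transitions — so analyses are reproducible regardless of
civil-time politics; the offset is a configuration value.

The lunar illuminated fraction is `(1 + cos i)/2` with the phase angle `i`
from the standard low-precision mean-elongation series (three Delaunay
arguments, seven periodic terms), accurate to ~0.01 — far below the effect
scales of interest.

## Covariates

* Human presence at three temporal scales anchored on each wildlife event:
  same-calendar-day human event count; same-ISO-week and same-calendar-month
  human event counts divided by active camera-days in the period. Weeks are
  ISO-8601 (Mon–Sun) and months calendar months — the simplest reproducible
  conventions. A period with zero active days yields a *missing* rate (the
  event is dropped and counted in the log), never zero: "no humans" and
  "camera off" must not be conflated.
* Trail and road density: total polyline length clipped to the closed 500 m
  disk around the station over the disk area, by exact per-segment quadratic
  clipping (no raster approximation). Doubling clipped length doubles
  density, and an empty layer is density 0.
* Distance to the urban-wildland boundary: minimum point-to-segment distance.
* Crown closure is consumed as a per-station point attribute (it proxies
  light availability in the camera's immediate vicinity, not in a buffer).
* Geometry is exact planar math; geographic inputs are projected with a local
  equirectangular frame anchored at the landscape reference point
  (~111,320 m per degree latitude).

## Model and inference

Per species: `N_i = β₀ + Σ β_k z_ik + ε_i`, `ε ~ N(0, σ²)`, predictors
z-scaled on the species' final analysis table (after row drops), flat
improper priors on coefficients completed by the reference prior
`p(σ²) ∝ 1/σ²`. The posterior is then available in closed form —
`β | y ~ multivariate-t(β̂, s²(XᵀX)⁻¹, n − p)` with `β̂` the least-squares
solution — and the analytic path is the default: the posterior mean equals
the least-squares estimate by construction, which every fit is tested
against. The sampling path is a conjugate Gibbs sampler (β | σ² normal,
σ² | β inverse-gamma) mirroring the MCMC workflow the analysis design calls
for: 4 chains sharing 100,000 total iterations (25,000 per chain; the
configured iteration budget is read as a total across chains), burn-in 5,000
per chain, thinning 1, overdispersed σ² starts, split-chain Gelman–Rubin
R-hat per parameter required < 1.1. Sampling and analytic paths agree to
Monte Carlo error (tested).

Credible intervals are equal-tailed — for symmetric Student-t marginals they
coincide with highest-density intervals and are simpler to test. Evidence
tiers: *strong* if the 95% CI excludes zero, *moderate* if only the 90% CI
does, else *none*; a 90% equal-tailed interval excluding zero implies
posterior sign probability ≥ 0.95 (asserted analytically in tests). Tier is
strength of *evidence* and is reported alongside, never instead of, the
effect size.

Temporal-scale selection: daily/weekly/monthly human presence measures are
mutually collinear, so each enters a univariate model compared to the
intercept-only null. With improper flat priors the marginal likelihood is
undefined, so Bayes factors use the Schwarz/BIC approximation
`BF = exp((BIC₀ − BIC₁)/2)` with the Gaussian log-likelihood at the
least-squares fit — a documented, reproducible proxy sharing the BF > 1
decision rule. The scale with the largest BF is included iff its BF > 1;
ties break deterministically daily > weekly > monthly. A collinearity screen
reports all predictor pairs with |Pearson r| ≥ 0.7.

Spatial diagnostics: Moran's I on per-station mean nocturnality (the most
literal reading of testing "species' nocturnality data"; residual-based
testing is available via the library API). Weights default to
row-standardised inverse distance — the choice is recorded in the output so
results are self-describing — with k-nearest-neighbour weights as an
alternative. The p-value is a two-sided permutation rank around the null
expectation −1/(n−1), with the add-one rule; station labels are permuted.

Activity curves: von Mises kernel densities on the 24 h clock circle, with
the ML-based Taylor plug-in concentration used in activity-overlap analysis
(`κ = (3nκ̂²I₂(2κ̂)/(4√π I₁(κ̂)²))^{2/5}`, κ̂ the ML von Mises fit, times an
`adjust` multiplier recorded with the output). Densities are per hour on a
512-point grid (refined automatically when the kernel is narrower than the
grid; the automatic concentration is capped at 10⁵, a width well under one
clock minute, so degenerate samples stay integrable). Curves use clock time
to match field practice; the solar-anchored response means a solar-anchored
curve variant is available by transforming input times.

## Synthetic study generator

The generator emulates the statistical structure the analysis assumes, at
the study's scale by default: 58 stations in a 20 × 20 km planar landscape,
March 2019 – September 2020, UTC−8 anchored at 49.4° N / −122.5° E, ~10%
camera-day outages, ~4.7 human detections per active camera-day with 87.8%
inside 09:00–18:00, six focal species with per-station event counts and
nocturnality intercepts matching the emulated campaign's totals (e.g. deer ≈
12.2 events/station, hares' intercept 9.23 h), and standardized covariate effects
of the magnitude the analysis is designed to detect (trail +0.8, road −0.9,
boundary −0.3, crown −0.35, lunar +0.27, weekly human +0.35 decimal
hours/SD). Residual SD defaults to 2.5 decimal hours — plausible scatter for
a response spanning [0, 12] — and is kept ≤ 2.5 so reflection bias (below)
stays negligible.

Design choices worth knowing:

* **Geometry is constructed to match the sampled covariates exactly.**
  Stations keep ≥ 1.1 km separation so 500 m buffers are disjoint; each
  station's trail/road polylines are straight chords laid inside its own
  buffer totalling exactly `density × πr²` meters; the boundary is the
  landscape's southern edge, so distance-to-boundary is the station's y.
  Recomputing covariates from the emitted geometry therefore reproduces the
  covariate table to float precision (tested at 1%).
* **Stratified covariates.** Line densities follow the deployment design:
  a fraction of stations sit on features (gamma-distributed density), the
  rest off-feature (small uniform density). This bounds standardized
  covariates to a few SD — important because the response is reflected into
  [0, 12], and unbounded covariate tails would push the linear predictor
  into the reflection region and bias recovery.
* **Human traffic.** Per active camera-day counts are Poisson with
  log-intensity `log(baseline) + 0.5·z_trail + u_s`,
  `u_s ~ N(0, 0.8)` a station effect for popularity variation beyond what
  density explains. Together these keep the realized correlation between
  human detection rates and trail density below the 0.7 collinearity screen,
  matching the covariate structure the screening step expects to pass.
  Detection times
  are uniform inside the diurnal window with probability 0.878, uniform
  outside otherwise — the simplest shape meeting the diurnal-concentration
  constraint.
* **Wildlife events.** Event dates per station × species are drawn without
  replacement from active days with ≥ 2 calendar days spacing, which
  structurally guarantees the 30-minute independence gap — filtering
  preserves event counts and the drawn nocturnality round-trips through the
  event/astro modules to within one second (tested). Nocturnality is the
  linear predictor plus Gaussian noise *reflected* at 0 and 12 (reflection
  rather than truncation-resampling keeps a defined, testable mapping); the
  timestamp sits that many hours before or after the date's solar noon by a
  fair coin (the statistic is side-blind), flipped when needed to stay on
  the same calendar date. The lunar covariate entering the linear predictor
  is evaluated at the date's solar noon (the realized time is unknown until
  the response is drawn); the truth table records the lunar fraction at the
  realized timestamp — exactly what the pipeline recomputes — so the lunar
  coefficient absorbs a ≤ 0.03 covariate perturbation, well inside the
  recovery tolerance.
* The per-species event-count law (Poisson) is a stand-in; nothing is
  claimed about the field system's abundance process.

What passing tests on synthetic data do **not** show about real data: the
generator has no detection-probability heterogeneity, no seasonal or weather
structure in effort or activity, no behavioural interactions among species,
no autocorrelated station covariates, and its linear-Gaussian-with-reflection
response is an idealisation — so calibration and recovery results certify
the estimator under its own assumptions, not robustness to field
misspecification.

## Numerical choices and problem sizes

* Solar formulas valid 1950–2100 (enforced); equation-of-time path agrees
  with an independent formulation to < 1 min; ±1 min is ~0.017 decimal
  hours, far below response scale.
* Cholesky solves for the posterior; a rank-deficient design raises
  immediately rather than silently pseudo-inverting. Constant predictors are
  rejected by the z-scaler with the column named.
* The statistical audit suite uses 500 calibration replicates (n = 500, 6
  predictors), 100 recovery replicates at the default 58-station scenario
  (~2,000 events each), 100 scale-selection replicates on a 25-station
  scenario where only the monthly rate carries signal, 200 Moran
  permutation-null replicates (999 permutations each), 10⁶ random timestamps
  for the nocturnality bound, and 1,000 random streams against the
  quadratic-time event-filter oracle.
* All randomness flows from explicit seeds; pipeline stages derive
  independent streams from one root seed, so re-runs are bit-identical.

## Known limitations

* The BIC Bayes factor is an approximation; alternative marginal-likelihood
  conventions can give different BF magnitudes (the >1 decision rule is the
  reproducible part).
* Reflection at the response bounds introduces a small attenuation for
  covariate configurations that push the linear predictor near 0 or 12.
* The independence-filter threshold is a convention; the chain vs
  event-start anchoring choice can matter for species that linger (both are
  implemented).
* Moran's I is a global test on station means; it will not localise
  autocorrelation nor correct the regression for it.
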