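# dielshift

Do humans push mammals into the night? `dielshift` analyses camera-trap
detection streams to quantify how direct human presence and land-use
infrastructure (recreation trails, restricted-access roads, proximity to the
urban-wildland boundary) shift the diel activity of medium-to-large mammals
toward nocturnality. It is written for ecologists working with multi-station
camera grids in recreated protected areas, and ships a synthetic study
generator with known ground truth so every stage of the analysis can be
validated end to end.

## The statistic and the model

Raw camera images are collapsed into **independent detection events**: images
of the same species at the same station belong to one event unless the gap to
the immediately preceding image strictly exceeds 30 minutes (1 minute for
humans). Each wildlife event gets a continuous **nocturnality** response

```
N(t) = min(|t − t_noon|, 24 − |t − t_noon|)   ∈ [0, 12]  (decimal hours)
```

the circular distance between the event timestamp and the solar noon of its
date (0 = solar noon, 12 = solar midnight), with solar transit computed from
the NOAA equation-of-time formulation.

Per species, nocturnality is modelled by a Bayesian linear regression with
flat coefficient priors and a 1/σ² residual-variance prior,

```
N_i = β₀ + Σ_k β_k z_ik + ε_i,   ε_i ~ Normal(0, σ²),
```

where every predictor is z-scaled (mean 0, SD 1), so the β_k are comparable
effect sizes in decimal hours per SD. Under the flat prior the coefficient
posterior is a multivariate Student-t centred on the least-squares solution;
`fit(method="analytic")` evaluates it in closed form, and
`fit(method="sampling")` runs a conjugate Gibbs sampler (4 chains, 100,000
iterations, burn-in 5,000) with split-chain Gelman–Rubin R-hat < 1.1
convergence checks.

Predictors: one human-presence measure — daily human detections, weekly or
monthly human detection rate per active camera-day, chosen by comparing each
univariate model to the intercept-only null with a BIC-approximate Bayes
factor (kept only when BF > 1) because the three measures are too collinear
to enter one model — plus trail density and road density within a 500 m
buffer (exact segment–circle clipping, m/m²), distance to the urban-wildland
boundary, lunar illuminated fraction, and crown closure. Evidence is tiered
by equal-tailed credible intervals: *strong* when the 95% CI excludes zero,
*moderate* when only the 90% CI does. Moran's I permutation tests check
per-station mean nocturnality for spatial autocorrelation, and von Mises
circular kernel densities summarise each species' diel activity curve.

## Worked example

Simulate a small 12-station, 6-month study and run the full pipeline:

```bash
dielshift simulate --out demo_data --seed 11 --n-stations 12 \
    --start 2019-03-01 --end 2019-09-01
dielshift run --data-dir demo_data --out-dir demo_out --seed 1
dielshift report --out-dir demo_out
```

which prints (abridged):

```
Independent detection events and nocturnality:
          species  n_events  mean_nocturnality  min_nocturnality  max_nocturnality
       black_bear        40               4.13              0.12              8.98
black_tailed_deer       150               6.07              0.01             11.92
           coyote        81               6.95              1.75             11.98
...

Temporal-scale selection (BIC Bayes factors vs null):
  black_bear: daily=0.16, weekly=0.184, monthly=0.189 -> chosen: none
  black_tailed_deer: daily=2.89e+03, weekly=7.51e+03, monthly=1.23e+04 -> chosen: monthly
...

Posterior estimates (z-scaled predictors):
          parameter            species  estimate     sd  ci90_lower  ci90_upper  ci95_lower  ci95_upper     tier     sign
 monthly_human_rate  black_tailed_deer     0.926  0.282       0.462       1.390       0.372       1.480   strong positive
       road_density  black_tailed_deer    -0.554  0.275      -1.007      -0.102      -1.095      -0.014   strong negative
...
```

Read: deer nocturnality rises 0.93 decimal hours per SD of monthly human
detection rate (strong evidence — the 95% CI 0.37 to 1.48 excludes zero),
and falls with road density. `mean_nocturnality` is hours from solar noon,
e.g. black bears (4.13) are the most diurnal species in this draw. The same
objects are available in Python:

```python
from dielshift import NocturnalityLM
model = NocturnalityLM.from_dataframe(table, species="coyote",
                                      predictors=[...])
res = model.fit()            # analytic flat-prior posterior
print(res.summary())         # estimates, 90/95% CIs, evidence tiers
res.conf_int(0.95)           # equal-tailed credible intervals
```

A single-event check from the command line:

```bash
$ dielshift solar --lat 49.4 --lon -122.5 --utc-offset -8 2019-06-15T22:10:00
solar noon:   12:10 local (12.1689 h)
nocturnality: 9.9978 decimal hours from solar noon
```

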