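# seedaging

Probit analysis of seed longevity under artificial aging, for seed-bank
scientists and conservation researchers who need to compare how fast
seed lots and species lose viability in storage.

## The problem and the model

Conservation seed banks store orthodox seeds for decades, but stored
seeds deteriorate. Comparative longevity is measured by artificial
aging: seeds are held at elevated temperature and humidity (here
45 °C / 60 % RH), withdrawn after increasing durations, and germinated.
Viability declines approximately linearly on the probit (normal
equivalent deviate) scale:

```
probit(v(t)) = Ki + b·t ,   b < 0
```

where `v(t)` is the viable fraction after `t` days of aging, `Ki` is
the initial viability in probits, and the slope `b` is the rate of
viability loss. The longevity measure is

```
σ = −1/b        days for viability to fall by one probit
p50 = Ki·σ      days for viability to fall to 50 %
```

σ is independent of a lot's starting viability, which makes it the
right trait for comparing lots and species; p50 confounds the two
(lots with the same σ but initial viabilities of 85 % vs 99.9 % differ
3-fold in p50).

Replicate germination dishes are binomial in expectation but
overdispersed in practice, so fits are quasi-binomial: binomial-likelihood
probit regression by IRLS, with all uncertainty scaled by the Pearson
dispersion φ = χ²/df.

The package implements the full analysis chain:

- **`seedaging.io`** — data model, CSV readers/writers, the reference
  aging design (10 durations from 0 to 72 d, 3 × 30 seeds).
- **`seedaging.probit`** — quasi-binomial probit engine: IRLS fits for
  single-lot and multi-lot designs, dispersion, Wald and nested
  quasi-F tests, σ/Ki/p50 with confidence intervals.
- **`seedaging.screening`** — seed-lot inclusion rules: initial
  germination ≥ 50 % (maximum over 0/1/5-day exposures, tolerating
  dormancy break), a significantly negative slope, and σ within the
  observed aging window.
- **`seedaging.species`** — within-species heterogeneity (lot × duration
  interaction F test), species-level σ from a common-slope model, and a
  logistic model of detection probability vs lots per species.
- **`seedaging.models`** — random-intercept REML mixed model of ln σ on
  within-species-scaled seed mass, mean annual temperature and
  precipitation, with type-III Wald tests and marginal/conditional R²;
  species-level OLS on family, seed mass, protein and oil content.
- **`seedaging.simulate`** — a hierarchical generator of synthetic
  germination datasets with known ground truth (beta-binomial dish
  counts, species random intercepts, covariate effects, dormancy).
- **`seedaging.pipeline` / `seedaging.cli`** — stage orchestration and a
  thin `seedaging` command (`run-all`, `fit-lots`, `screen`,
  `compare-species`, `lmm`, `species-models`, `simulate`).

## Worked example

`examples/01_fit_single_lot.py` simulates one lot (true Ki = 2 probits,
true σ = 20 days, mild overdispersion) and fits it:

```
slope             -0.0470 probits/day  (rate of viability loss)
sigma               21.28 days        (days per probit lost; true 20)
95% CI           (18.50, 25.03) days
Ki                  2.008 probits     = 97.8% initial viability
p50 = Ki*sigma      42.73 days        (time to 50% viability)
dispersion phi       1.67             (>1 means overdispersed dishes)
```

The fitted slope of −0.047 probits/day back-transforms to σ ≈ 21 days:
each three weeks of aging at 45 °C/60 % RH costs this lot one probit of
viability, and it would cross 50 % viability after ~43 days.
`examples/02_screen_and_compare_species.py` screens a multi-species
dataset and runs the heterogeneity tests;
`examples/03_predictor_lmm.py` fits the mixed model and prints the R²
decomposition (species identity dominates; lot-level predictors explain
only a small share of the rest).

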