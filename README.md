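# inbrex

Statistical machinery for inbreeding experiments on panels of isofemale
lines: does sexually antagonistic (SA) genetic variation make genotypes
vulnerable to inbreeding?

In the design this package models, a panel of ~41 isofemale lines — each a
laboratory line founded from one wild-caught mated pair, so each captures a
sample of segregating genetic variation — is first assayed for line-mean
male and female fitness (lifetime offspring production). Around 20 replicate
lineages per line are then forced through single-pair full-sib matings for
up to 10 generations; a lineage goes extinct when it can no longer furnish
one male and one female to parent the next generation. The analysis asks
whether extinction risk is predicted by where a line sits on the spectrum
from male-benefit/female-detriment to female-benefit/male-detriment
genotypes, and how much of the observed extinction mere demography (low
fecundity plus unlucky sex ratios) would have produced without inbreeding.

## What the package provides

- **Derived fitness axes** — log-transform and variance-standardize
  line-mean fitness within each sex, then rotate the (male, female)
  coordinate system clockwise 45°:
  `antagonism = (m − f)/√2` (male-benefit ↔ female-benefit) and
  `concordance = (m + f)/√2` (generally high ↔ generally low fitness).
  Available as an sklearn-style transformer (`AntagonismConcordance`) or
  one call (`derive_axes`).
- **Mixed-effects Cox regression** of lineage extinction with a Gaussian
  per-line random intercept (shared log-normal frailty), fitted by
  penalized Newton–Raphson inside a bounded search over the frailty
  variance (Laplace-approximate integrated partial likelihood), Efron tie
  handling by default. `CoxPH` and `CoxFrailty` are sklearn-style
  estimators; `fit_cox_ph` / `fit_cox_frailty` wrap them for
  records + covariate-table DataFrames. Leave-one-out dfbeta outlier
  screening, AIC comparison and likelihood-ratio tests included.
- **Demographic extinction forecasts** isolating what fecundity alone
  explains: a Monte-Carlo fecundity-only simulator (lineage survives a
  generation iff ≥2 offspring with both sexes present) and
  geometric/linear projections of first-generation extinction rates.
- **Follow-up assay statistics** — Pearson chi-square on zero-offspring
  rates, a linear mixed model (line, lineage-in-line and assay-date random
  effects) for nonzero offspring counts, and extreme-line selection along
  PC1 of (antagonism, extinction risk).
- **A synthetic-data generator** (`SimConfig` + `generate_*`) that emulates
  the study design with known ground truth — intersexual correlation −0.51,
  planted hazard effects (0.20, −0.14), frailty variance 0.14, baseline
  hazard calibrated to ~78% overall extinction — driving every recovery and
  calibration experiment in the test suite.
- **A CLI** (`inbrex`) and an end-to-end pipeline producing a reproducible
  JSON run report.

## Worked example

```python
from inbrex import (SimConfig, generate_line_fitness, generate_lineage_histories,
                    generate_fecundities, derive_axes, fit_cox_frailty,
                    simulate_fecundity_extinction)

cfg = SimConfig(seed=1)                     # 41 lines x 20 lineages, 10 generations
lines = generate_line_fitness(cfg)
records, truth = generate_lineage_histories(lines, cfg)
axes = derive_axes(lines)

fit = fit_cox_frailty(records, axes)        # mixed Cox, line as Gaussian frailty
print(fit.summary().round(3))
print(f"frailty variance: {fit.frailty_variance_:.3f}")
print(f"observed extinction: {records['event'].mean():.1%}")

fec = generate_fecundities(lines, cfg)
fc = simulate_fecundity_extinction(fec, replicates=5000, seed=1)
print(f"fecundity-only forecast: {fc.overall:.1%}")
```

prints

```
              coef     se      z      p
antagonism   0.227  0.070  3.238  0.001
concordance -0.100  0.103 -0.977  0.328
frailty variance: 0.201
observed extinction: 76.3%
fecundity-only forecast: 0.4%
```

Read: in this simulated panel, male-benefit/female-detriment lines go
extinct significantly faster (positive antagonism coefficient, log
hazard-ratio per unit of the derived axis), the concordance trend is
negative (generally low-fitness lines fare worse) but not significant in
this single realization, and substantial per-line heterogeneity remains
beyond the two axes (frailty variance on the log-hazard scale). The
fecundity-only forecast shows that demography without inbreeding explains
almost none of the 76% observed extinction — the signature of inbreeding
depression. The same stages run from the shell:

```sh
inbrex simulate all --out data/
inbrex axes --in data/line_fitness.csv --out data/axes.csv
inbrex survival fit --records data/records.csv --covars data/axes.csv
inbrex pipeline run --simulate --out run/
```

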