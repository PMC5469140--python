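# Methods

This note documents the models, algorithms, numerical choices and known
limitations behind `inbrex`. The package analyses single-pair full-sib
inbreeding experiments on panels of isofemale lines — the design in which
~20 replicate lineages per line are inbred for up to 10 generations and the
question is which genotypes (lines) tolerate inbreeding — and ships a
synthetic-data generator that emulates that design with known ground truth.

## Derived fitness axes

Input: one mean male and one mean female lifetime offspring count per
isofemale line. Both are natural-log transformed and variance-standardized
(mean 0, sample variance 1 with the n−1 denominator) within each sex; the
base of the log is immaterial because standardization absorbs it. The
coordinate system is then rotated clockwise by 45°:

    antagonism  = (male_std − female_std) / √2
    concordance = (male_std + female_std) / √2

The orthonormal (1/√2) scaling makes the map a true rotation: per-line
squared length is preserved, the inverse is exact, and the two derived axes
are exactly uncorrelated when both inputs are standardized. Positive
antagonism denotes male-benefit/female-detriment genotypes; positive
concordance denotes generally high-fitness genotypes. The derived axes are
**not** re-standardized by default. Under the pure rotation the two Cox
parameterizations (antagonism/concordance vs. female/male fitness) are
exact linear reparameterizations of each other,

    β_male = (β_a + β_c)/√2,   β_female = (β_c − β_a)/√2,

which makes coefficient tables in the two parameterizations mutually
consistent; re-standardizing the derived axes (available via a flag) would
break this exact map whenever the axes' variances differ. That
self-consistency is why no re-standardization is the default.

Degenerate inputs: non-positive fitness means are a domain error (log is
undefined); zero variance within a sex is a degenerate-input error; at
least two lines are required (two suffice for a sample variance, and the
two-point case is useful as an analytic check).

## Mixed-effects Cox model of lineage extinction

The survival unit is the lineage; `time` is the extinction generation (or
the censoring horizon, generation 10 by default) and `event` marks
extinction. Covariates are line-level. Line identity enters as a Gaussian
random intercept b_j ~ N(0, σ²) on the log-hazard (shared log-normal
frailty):

    h_ij(t) = h_0(t) · exp(x_j'β + b_j).

Estimation follows the penalized-partial-likelihood / Laplace approach.
For fixed σ², an inner Newton–Raphson maximizes the penalized log partial
likelihood lpl(β, b) − b'b/(2σ²) jointly over (β, b), with step-halving and
convergence declared when the penalized log-likelihood changes by less than
1e-8. The Laplace-approximate integrated log-likelihood at the joint mode is

    ILL(σ²) = lpl(β̂, b̂) − b̂'b̂/(2σ²) − ½ log det(I_q + σ² · I_bb),

where I_bb is the random-effect block of the observed information of the
unpenalized partial likelihood. This form is numerically stable at σ² → 0,
where it reduces to the fixed-effects partial log-likelihood. The outer
problem maximizes ILL over σ² by a bounded one-dimensional search on
[0, 10] with absolute tolerance 1e-4; if the optimum is driven to the lower
bound, or the σ² = 0 limit attains an equal or higher ILL, the variance is
reported as exactly 0 with a boundary flag and the fit falls back to the
plain Cox solution. Warm-starting the inner solver across outer iterations
makes a full fit on ~800 lineages take well under a second.

Ties are handled by the Efron approximation by default — important because
discrete generation times produce heavy ties (hundreds of events at each of
10 distinct times) — with Breslow available behind a flag. The partial
likelihood, its gradient and its observed information are evaluated in
closed form, vectorized over unique event times (risk-set quantities come
from suffix cumulative sums; all Efron tie corrections collapse to weighted
row sums), so both tie-free and heavily tied data cost O(n·k²) numpy work
per evaluation with no Python-level loop.

Standard errors of the fixed effects come from the fixed-effect block of
the inverse of the penalized observed information at the optimum; z = β/se
with two-sided normal p-values. AIC is −2·ILL + 2·(p + 1 if σ² was
estimated); the frailty variance counts as one parameter. AIC differences
are reported as null minus fitted (positive favours the fitted model) and
comparisons across different record sets are refused. The likelihood-ratio
test checks nesting on parameter-name sets; identical models return
(χ² = 0, df = 0, p = 1) by convention.

With σ² fixed at 0 the implementation reduces exactly to standard Cox
regression; the test suite verifies agreement with an independent
implementation (lifelines) to 1e-6 on coefficients, standard errors and
log-likelihood, on tied and untied data.

### Per-line extinction-risk scores

A null model (no fixed covariates, line frailty only) yields predicted
random intercepts — the posterior modes b̂ — used as per-line
"extinction risk" scores. They are approximately centered on zero and, at
20 lineages per line, rank-correlate strongly (ρ > 0.7 in recovery tests)
with planted log-frailties.

### Influence screen

Outliers are screened on the fixed-effects Cox fit by exact leave-one-out
refits: at ~800 records a refit warm-started from the full-data solution
converges in a few iterations, so the exact screen is affordable and
one-step dfbeta approximations are unnecessary. Each record's delta is the
full-fit coefficient minus the leave-one-out coefficient; records whose
|delta| exceeds mean + k·sd (default k = 3) of the |delta| distribution for
any coefficient are flagged, and flags are tallied per line. Exclusions
whose refit fails leave a missing delta and the screen continues.

One subtlety is intrinsic to leave-one-out screening of *clustered*
outliers: removing one record of an aberrant line leaves its remaining
records anchoring the fit, so per-record deltas are diluted roughly in
proportion to the line's replication. The screen therefore also aggregates
influence per line — the mean |delta| of a line's records, normalized by
the across-line median — and ranks lines by this score; a line whose
lineages are collectively discrepant stands out at the top of this ranking
even when few of its individual records cross the record-level threshold.
A line with a majority of its records flagged is reported as a cluster and
is the pipeline's criterion for refitting with that line excluded (derived
axes are recomputed on the remaining lines before the refit).

## Demographic extinction forecasts

Both forecasts estimate the extinction expected **without** continued
inbreeding; their point is to quantify how much of the observed extinction
demography alone could explain.

**Fecundity-only simulation.** Per lineage and generation, a lifetime
offspring count is resampled with replacement from the line's observed
fecundity samples (draws iid across generations — deliberately excluding
any inbreeding effect), and offspring sexes are iid Bernoulli(1/2). The
lineage survives the generation iff at least two offspring including one of
each sex emerged (a single full-sib pair must parent the next generation).
For a constant brood of n the per-generation survival probability is
1 − 2^(1−n) (n ≥ 2), giving the closed-form G-generation extinction
probability 1 − (1 − 2^(1−n))^G against which the simulator is validated.
The sex ratio is configurable for sensitivity analysis. A negative-binomial
parametric draw is available for synthetic use.

**First-generation projection.** With p̂₁ the per-line fraction of lineages
extinct in the first generation, the forecast compounds either
geometrically, 1 − (1 − p̂₁)^G (the default: the first-generation hazard
repeated independently), or linearly, min(1, G·p̂₁). The linear form is the
upper envelope of the geometric one for every p̂₁ and G, so both are
reported and the compounding convention is recorded in the output metadata.
Overall values are lineage-weighted means.

## Follow-up assay analyses

Offspring counts from follow-up fecundity/fertility assays are
zero-inflated. The zero rate is compared between the male-benefit and
female-benefit categories by a Pearson chi-square on the 2×2
zero/nonzero × category table, without continuity correction (matching the
single-df χ² style of such analyses); empty margins make the table
untestable and raise. Zeros are then excluded and the remaining counts
analysed with a linear mixed model: offspring ~ category + base_cohort with
random intercepts for line, lineage-within-line and assay date. The
category effect is tested by a likelihood ratio between maximum-likelihood
fits with and without category (1 df).

Implementation: statsmodels MixedLM with a single artificial group and one
variance component per random factor (the standard device for crossed
random effects in MixedLM), with `re_formula="0"` so no random intercept is
attached to the artificial group — that intercept would be confounded with
the fixed intercept and destabilizes the likelihood. Gradient optimizers
fail on these likelihoods often enough to corrupt likelihood-ratio
statistics, so every fit runs both L-BFGS and Powell and keeps the higher
converged likelihood. The full and null models are always compared under
the same random-effects specification: a variance estimated at the zero
boundary is a valid ML solution and is kept (dropping it from one side
would bias the likelihood ratio — in particular, the null model needs the
line component to absorb the category contrast); a component is removed,
with a warning and from both models, only when the fit itself fails.

**Calibration caveat.** The category contrast is a between-line effect. With
only 3 lines per category — the size a follow-up on extreme lines
necessarily has — the χ²₁ reference for the category LRT is markedly
anticonservative (the effective reference is closer to an F distribution
with a handful of denominator degrees of freedom, and maximum-likelihood
estimation of the line variance adds further liberality). The calibration
experiments in the test suite therefore use a line-rich design — 20 lines
per category with light within-line replication (2 lineages × 3 assays),
keeping the between-line information high relative to the line-variance
estimate — where the χ²₁ reference is accurate; inferences from the 3+3
design should be treated as descriptive.

**Extreme-line selection.** Lines are ranked on the first principal
component of the standardized (antagonism, extinction-risk) pair — the
eigenvector of their 2×2 correlation matrix (correlation, not covariance,
because the two scores have unrelated natural scales) — oriented so that
positive PC1 correlates with antagonism; the 3 most-positive
(male-benefit/high-extinction) and 3 most-negative
(female-benefit/low-extinction) lines are returned. If one score is
constant the ranking degenerates to the other score, and the ranking is
invariant to affine rescaling of either input.

## Synthetic-data generator

The generator is a pure function of a `SimConfig` (including its seed; each
sub-generator draws from an independent stream derived from the global
seed). Defaults emulate the modelled study design:

| knob | default | rationale |
|---|---|---|
| n_lines × lineages_per_line | 41 × 20 | panel size of the modelled design |
| max_generations | 10 | inbreeding horizon |
| intersexual_correlation | −0.51 | strongly sexually antagonistic panel |
| β_antagonism, β_concordance | 0.20, −0.14 | planted log-hazard effects |
| frailty_variance | 0.14 | per-line heterogeneity beyond the axes |
| baseline_hazard | 0.159077 per generation | calibrated (below) |
| log-scale fitness | male: log 40 ± 0.5; female: log 60 ± 0.3 | lifetime offspring counts at seed-beetle scale; male fitness noisier, reflecting the larger environmental variance of male reproductive success |
| fecundity | NB, mean = female fitness, dispersion 4 | overdispersed counts |
| follow-up assays | zero rate 0.12; effects: line 5, lineage 4, date 3, cohort 2, residual 15 around mean 60 | zero-inflated counts with nested structure at assay scale |

The baseline hazard was calibrated once — not re-fit silently — by
root-finding on the expected overall extinction proportion: the linear
predictor is treated as Gaussian with variance β_a²(1−r) + β_c²(1+r) + σ²
(the derived axes have variances 1∓r when both sexes are standardized) and
E[1 − exp(−G·h₀·e^η)] evaluated by Gauss–Hermite quadrature; h₀ = 0.159077
gives 77.8% expected extinction over 10 generations, the realistic severe
regime for this design. `calibrate_baseline_hazard` reproduces the
calibration deterministically.

Two time modes share the same marginal extinction probability:
*continuous* draws exponential event times with rate h₀·e^η censored at the
horizon (tie-free — the default, and the mode used for parameter-recovery
experiments, because tie-free data make partial-likelihood recovery
unbiased); *discrete* applies the grouped proportional-hazards
(complementary log-log) per-generation probability 1 − exp(−h₀·e^η) on
generations 1..G, which is the realistic shape of generation-resolution
data.

What the generator does **not** emulate: inbreeding depression accelerating
over generations (hazards are time-constant given the line), unequal
lineage counts per line, modes of extinction, selection during line
maintenance, or any genetic mechanism (SA loci, dominance, linked load).
Passing recovery tests therefore demonstrate correctness of the estimators
under the generating model, not robustness to those real-data features.

## Validation experiment sizes

The replicated experiments run at the full design size (41 × 20,
continuous time): 200 replicates for parameter recovery (mean recovered
fixed effects within 10% relative error; mean frailty variance within 0.05
absolute — the Laplace ML estimate of σ² carries a small downward
finite-sample bias, well inside that band) and 500 null replicates for
each type-I calibration. The interaction LRT is calibrated with
fixed-effects fits on data generated without line heterogeneity — the null
model the fixed-effects test assumes; the LRT between Laplace-approximate
integrated likelihoods of frailty models is itself slightly liberal, a
known property of approximate integrated likelihoods, and is documented
rather than hidden.
The demographic simulator is checked against its closed form at 10⁵
replicates within 3 binomial standard errors.

## Known limitations

- The Laplace approximation yields a mildly downward-biased σ̂² and a
  slightly liberal LRT between frailty fits at this design size (above).
- The influence screen's record-level threshold under-detects clustered
  outliers by construction; the line-level aggregation addresses this but
  its threshold (majority of records flagged) is a pragmatic choice, not a
  calibrated test.
- The category LMM's χ²₁ reference is unreliable at 3 lines per category.
- No competing risks across extinction modes, no time-varying covariates,
  no stratified baselines, and interval censoring is ignored beyond
  generation granularity.
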