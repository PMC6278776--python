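# Methods

## Measurement model

A *sample* is the multiset of allele sizes (CTG-repeat units, stored as
reals because gel sizing is continuous) obtained by single-molecule
small-pool PCR for one patient, tissue and time point.  Samples with
fewer than 200 sized alleles are flagged, not rejected: the 200-allele
floor is the sizing QC of the underlying assay, and downstream statistics
remain well defined below it.

**Percentiles.**  All percentiles use linear interpolation between order
statistics at rank h = (n − 1)·q/100 + 1 (numpy's default `linear`
method).  This convention is what produces the half-integer percentile
values seen in sized-allele tables; alternatives can be obtained by
operating on the raw arrays directly.  ePAL is the 10th percentile, SI
the 90th − 10th percentile range.  Both are invariant to row order and
(up to one order-statistic spacing) to duplication of the sample.

**Modal length.**  Sizes are rounded to whole repeats and tallied into an
integer histogram; the histogram is smoothed with a Gaussian kernel
before the argmax is taken.  The default bandwidth is Silverman's
rule-of-thumb on the raw sizes, `bandwidth=0` disables smoothing, and
ties break toward the smaller length so the estimate is deterministic.
Smoothing matters because a 200-draw histogram over a distribution that
spans hundreds of repeat values is sparse; the smoothed argmax behaves
like the centre of the densest region rather than a single lucky bin.

**5′-end view.**  For an interrupted expansion the interrupted part is
defined from the first non-CTG block to the 3′ end (pure CTG runs lying
between interruptions count toward it), with the CCGCTG hexamer
contributing two trinucleotides per repeat.  Subtracting this constant
from every allele yields the 5′-end view; SI is invariant under the
shift, ePAL and the mode move down by the constant.  A per-patient
override is accepted and, when present, is authoritative: published
per-patient mode differences exceed naive pattern arithmetic by two
repeats for several patients, and the package does not guess at the
cause.  Patterns whose interior blocks have unknown counts *require* the
override.

## Regression suite

Models are `ModelSpec`s — response and predictor columns with transforms
(identity, log10, ln) and optional fixed coefficients — fitted by OLS
(statsmodels) on the transformed scale.  Defaults:

| model | form | role |
|---|---|---|
| M8 | log10(SI) ~ ePAL + AS | instability vs length and age |
| M8_5prime | log10(SI₅′) ~ ePAL₅′ + AS | the same on the 5′-end view |
| M9 | log10(AO) ~ ePAL | onset vs length |
| M10 | log10(AO) ~ log10(ePAL) | onset vs length (log–log) |
| M11 | M10 + standardised M8 residual | onset vs length and individual instability |
| INCR | increment ~ mode + interval | expected size increment |

The exact functional forms used in the original reference-cohort work are
not published in the main text, so these defaults are an assumption of
this package, chosen for scale stability (logs on the strictly positive,
right-skewed responses) and documented as configuration rather than
doctrine; any form is expressible as a `ModelSpec`, including fixed
published coefficients that bypass fitting.  Interaction terms are
excluded by default.  R² is reported unadjusted.  Models are refit
separately per sampling time point.

Residuals live on the transformed response scale and are standardised to
mean 0, SD 1 using the sample SD (ddof = 1); the standardised M8
residual is attached per subject as the M11 covariate.  Rank-deficient
designs, non-positive responses under a log transform (reported with the
offending subject ids) and subjects missing from the M8 fit are errors,
not warnings.

## Comparison matrix

Six families, all two-tailed at α = 0.05 with no multiplicity
correction; any comparison with missing inputs is skipped with a logged
reason:

(a) per-patient blood-vs-buccal AFD rank-sum tests (latest matched time
point); (b) per-patient t1-vs-t2 blood AFD rank-sum tests; (c) per-group
observed-vs-expected SI signed-rank tests (expected from the M8 fit,
natural scale); (d) per-group observed-vs-expected increment signed-rank
tests (expected from the INCR fit on the reference increments); (e)
interrupted-vs-reference and control-vs-reference rank-sum tests on
standardised M8/M10/M11 residuals; (f) within-group paired signed-rank
tests of M11 vs M10 standardised residuals.

**Rank-sum.**  W is the Mann–Whitney count of the first sample (pairs
won plus half ties); the first sample's identity (earlier time point,
blood, study group) is recorded as `orientation`, and the reflection
identity W → n₁n₂ − W with identical p makes either orientation
recoverable.  When the pooled data are tie-free and n₁n₂ ≤ 400 the
two-sided p is exact, computed from the Gaussian-binomial generating
function of the null U distribution and doubled (capped at 1).
Otherwise a normal approximation with tie correction and a 0.5
continuity correction is used.

**Signed-rank.**  Zero differences are dropped, absolute differences get
midranks, V is the sum of positive-difference ranks.  For n ≤ 25 the
two-sided p is exact conditional on the observed tie pattern, by
subset-sum counting over all 2ⁿ sign assignments (doubled ranks keep the
lattice integral); above that, normal approximation with tie and
continuity corrections.  The all-negative configurations give V = 0 with
p = 2/2ⁿ, e.g. 0.03125 at n = 6 and 0.015625 at n = 7.

**Normality gate.**  Shapiro–Wilk (scipy) is run and recorded for
3 ≤ n ≤ 5000 with non-zero variance, but the harness always proceeds
with the nonparametric test — the gate documents, it does not switch.

These primitives are implemented in-house because the exactness
conventions are part of the analysis contract; scipy's implementations
serve as independent cross-checks in the test suite.

## Synthetic cohorts

The generator produces data with the statistical structure the analysis
assumes, not a mechanistic model of repeat metabolism.

**Somatic process.**  Each of `n_lineages` (default 300) cell lineages
carries one expanded allele starting at the progenitor length L₀.
Mutation events arrive as a Poisson process at rate
r · f · m · u · L₀ per year, where r is `expansion_rate` (0.003 events
per repeat-year), f the interruption stabilization factor (default 0.4
for interrupted alleles, 1 otherwise), m a per-subject lognormal
propensity multiplier (`individual_log_sd` = 0.15 on the log scale) and
u a per-lineage gamma factor (shape 2, mean 1).  Each event expands the
allele by a geometric step (mean 2.5 repeats) with probability 0.85 and
contracts it otherwise; lengths are clipped to [50, 4000] repeats.  The
rate is tied to the *progenitor* length and held constant in time: a
current-length-proportional rate makes fast lineages grow exponentially,
which detaches the 10th percentile from the progenitor length and
destroys the very property (a stable lower AFD edge) that makes ePAL a
usable estimator.  Lineage-rate heterogeneity is what anchors that lower
edge while the upper tail expands, giving the right-skewed AFDs the
assay produces.

**Observation.**  Small-pool PCR reactions each amplify Poisson(λ = 7)
molecules drawn with replacement from the lineage population; observed
sizes are multiplied by lognormal noise with CV 0.02 (mean 1); molecules
below 55 repeats are lost to detection; reactions accumulate until at
least 200 alleles are sized.

**Cohorts.**  The reference cohort holds 136 uninterrupted-expansion
subjects (121 symptomatic) with ePAL ~ U(120, 800), first sampling age
~ U(18, 60) and a second sampling 2.5–11 years later.  Age at onset is
drawn as log10(AO) = 3.35 − 0.80·log10(ePAL) − 0.09·z + ε, ε ~ N(0,
0.15²), where z is the subject's standardised log instability propensity
— for interrupted study subjects z includes log f, which is exactly what
makes interruption carriers later-onset than their length predicts and
gives the residual-as-covariate model signal to find.  The study cohort
is 7 interrupted + 4 control subjects with paired blood samplings
(2.5–4 y and 4–11 y intervals respectively), buccal samples for a subset
(buccal tissue: progenitor offset +100 repeats, rate factor 0.5), and
synthetic interruption-pattern strings with matching overrides, emitted
in the package's own TSV input formats.

**Calibration.**  The defaults were set so that refitting M8 on the
default reference cohort explains ≈ 90% of SI variability (measured
86–93% across seeds at n = 136), with the onset models in the ≈ 40–60%
band and a visible M11-over-M10 improvement.  The per-year mutation
rates and step sizes of real *DMPK* somatic mosaicism are unknown;
these values are calibration knobs, documented as such.

**What the simulator does not emulate.**  PCR stutter and heteroduplex
artifacts; length-dependent amplification bias; acceleration of
expansion late in life — with a time-constant rate the modal increment
between two samplings a few years apart is small (≈ 5–15 repeats)
relative to the published per-patient increments, so the increment
model's explained variance is low in synthetic data and
observed-vs-expected increment comparisons are under-powered there;
intergenerational transmission; methylation or repair-gene effects.
Passing tests therefore certify the pipeline's statistics and the
qualitative group structure (stabilized alleles → lower SI, later
onset), not quantitative increment dynamics of real cohorts.

## Numerical choices and degenerate inputs

- Percentile q outside (0, 100), empty samples, non-positive sizes,
  all-zero signed-rank differences, constant Shapiro–Wilk input and
  subtraction constants ≥ the smallest allele all raise errors.
- Modal tie-break: smallest length.  Standardisation: ddof = 1; a
  perfect fit (zero residual variance) yields all-zero standardised
  residuals instead of a division error.
- Exactness thresholds (n₁n₂ ≤ 400 tie-free for rank-sum, n ≤ 25 for
  signed-rank) follow the dominant convention in standard statistical
  software and are configurable per call.
- All simulator randomness flows from one `numpy` Generator seeded by
  the caller; identical seeds give identical cohorts.

## Problem sizes in the test suite

Monte-Carlo-heavy checks (type-I error over 400 seeds, power and
sign-consistency over 20–25 seeds, stabilization contrasts over 200
replicates) run on a reduced profile — 30-subject reference cohorts, 60
lineages, 80 alleles per sample — chosen as the smallest sizes at which
the contrasts of interest remain clearly resolved; the calibration check
and the acceptance script use the full default cohort (136 subjects, 300
lineages, ≥ 200 alleles).
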