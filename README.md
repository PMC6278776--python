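# somamosaic

Somatic instability of expanded *DMPK* CTG repeats — the mutation that
causes myotonic dystrophy type 1 (DM1) — quantified from single-molecule
small-pool PCR allele-size data, and linked to age at onset through a
residual-as-covariate regression suite.  The package is written for human
geneticists studying tandem-repeat diseases who need a reproducible,
scriptable version of this analysis: per-sample allele-frequency-
distribution (AFD) statistics, the linear-model chain, the nonparametric
comparison matrix against a large reference cohort, and a synthetic-cohort
simulator with the same statistical structure for power and calibration
work.

## The analysis in brief

Each sample is a list of individually sized expanded alleles (in CTG
repeat units) from one patient, tissue (blood or buccal) and time point.
From its empirical AFD the pipeline computes:

- **ePAL**, the estimated progenitor allele length — the 10th percentile
  of the AFD (somatic mutation is expansion-biased, so the inherited
  allele sits near the lower edge);
- **SI**, the observed somatic instability — the 90th − 10th percentile
  range of the AFD;
- the **modal expansion size** (whole repeats, smoothed integer
  histogram), whose change between two samplings is the observed size
  increment;
- a **5′-end view** of interrupted expansions, obtained by subtracting
  the interruption-containing 3′ block (parsed from pattern strings such
  as `(CTG)n CTC (CTG)26`, or supplied as a per-patient override) from
  every allele.

The model suite, fitted by OLS on configurable transforms:

- model 8\*: `log10(SI) ~ ePAL + AS` (AS = age at sampling), whose
  **standardised residual** measures individual-specific instability;
- models 9\*/10\*: `log10(AO) ~ ePAL` and `log10(AO) ~ log10(ePAL)`
  (AO = age at onset);
- model 11\*: model 10\* plus the standardised SI residual from model
  8\* — the test of whether individual-specific instability modifies
  onset beyond expansion size;
- an increment model: `increment ~ mode + interval`.

The comparison matrix reproduces the analysis' tests: per-patient
blood-vs-buccal and first-vs-second time point AFD comparisons
(Wilcoxon–Mann–Whitney, exact enumeration for small tie-free samples),
per-group observed-vs-expected SI and increment comparisons (Wilcoxon
signed-rank, exact by sign-pattern enumeration), and group comparisons of
standardised residuals against the reference cohort, with a Shapiro–Wilk
normality gate recorded before each rank test.  All p-values are
two-tailed at α = 0.05, with no multiplicity correction.

The simulator evolves cell lineages as compound-Poisson length walks
(expansion-biased geometric steps, event rate proportional to the
progenitor length, gamma-distributed lineage heterogeneity), observes
them through Poisson-diluted small-pool PCR with lognormal sizing noise,
and draws age at onset from ePAL and the subject's true instability
propensity.  Repeat interruptions act as a multiplicative stabilization
factor *f* ≤ 1 on the whole allele's event rate.  See
[docs/methods.md](docs/methods.md) for model details and defaults.

## Worked example

```python
from somamosaic import (CohortSpec, SimulationConfig, StudyCohortSpec,
                        generate_reference_cohort, generate_study_cohort,
                        run_comparison_matrix)

sim = SimulationConfig()                      # somatic process + small-pool PCR
cohort = CohortSpec()                         # 136-subject reference cohort
reference = generate_reference_cohort(cohort, sim, seed=1)
records, _ = generate_study_cohort(cohort, StudyCohortSpec(), sim, seed=2)
matrix = run_comparison_matrix(records, reference)

print(matrix.fits["M8/t1"].summary())
for r in matrix.results:
    if r.family == "si_obs_vs_exp" and r.timepoint == "t1":
        print(f"{r.label:>12}: V = {r.statistic:.0f}, p = {r.p_two_tailed:.3g}")
```

prints

```
Model M8: log10(si) ~ epal + age_at_sampling
n = 147    R^2 = 0.8237
term                          coef          se
intercept                    1.315     0.03449
epal                     0.0009164   4.782e-05
age_at_sampling            0.01021   0.0007792

 interrupted: V = 0, p = 0.0156
     control: V = 10, p = 0.125
   reference: V = 5370, p = 0.122
```

Reading this: instability grows with progenitor length and age
(both coefficients positive); every one of the seven simulated
interruption carriers shows less instability than the model predicts
(all seven paired differences negative, so the signed-rank statistic
V = 0 and the exact two-tailed p is 2/2⁷ ≈ 0.016), while the
uninterrupted control and reference groups scatter around their expected
values.

The same pipeline runs from the shell:

```bash
somamosaic simulate --seed 7 --out-dir demo/
somamosaic run --alleles demo/alleles.tsv --patients demo/patients.tsv \
               --reference demo/reference.tsv --out demo/report/
```

writing the per-patient summary tables (`table1.tsv`, `table2.tsv`), all
test results (`tests.tsv`, with skipped comparisons and reasons in
`skipped.tsv`), density-curve and residual-scatter coordinates, and a
full-precision `bundle.json`.

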