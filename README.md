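# ctcohort

Case–control qRT-PCR cohort analysis for postmortem brain expression
studies: ΔΔCt quantification, a comparison battery with correlation-scale
effect sizes, control-anchored **high-expressor subgroup detection** with an
iteratively KS-trimmed "normal core" estimator, covariate screening, and a
hierarchical R² decomposition that separates tissue-pH effects from a focal
transcript's contribution. A seeded synthetic-cohort generator makes every
stage testable end to end without any external data.

## Who it is for

Groups running TaqMan-style qRT-PCR on case–control tissue collections
(e.g. schizophrenia vs unaffected-control prefrontal cortex), where group
differences are often driven not by a uniform shift but by a *subset* of
cases expressing a transcript far above the population core, and where
postmortem covariates — tissue pH above all — confound naive correlations
between transcripts.

## The model

**Quantification.** Each sample is measured in technical triplicate;
replicates deviating more than 0.5 Ct from the triplicate median are
dropped. For target gene *g* in sample *i*,

    ΔCt_i,g  = Ct_i,g − geomean(Ct of ≥3 housekeeper genes in sample i)
    ΔΔCt_i,g = ΔCt_i,g − mean ΔCt of the calibrator (control) group
    rq_i,g   = 2^(−ΔΔCt_i,g)

so rq = 1 is the control-group average and rq = 2 is roughly a doubling of
transcript. Population outliers are flagged (never silently dropped) by an
iterative two-sided Grubbs test.

**High-expressor subgroup.** A sample is a *high expressor* when
rq > median(controls) + 1.25 × IQR(controls). The high/normal split is
cross-tabulated against diagnosis (Pearson χ², no continuity correction)
and summarized as a risk ratio. The *normal core* of the rq distribution is
estimated by reiteratively removing the single highest value until a
Lilliefors-corrected Kolmogorov–Smirnov test stops rejecting normality at
α = 0.05; the flagged subgroup's elevation is then reported in core-SD
units, (mean(flagged) − core mean)/core SD.

**Effect sizes** follow the r conventions: r = √(t²/(t²+df)),
r = |Z|/√N, r = √(χ²/N).

**Variance decomposition.** For a dependent marker transcript *y*,
predictor transcript *x* and tissue pH, three OLS fits give R²(x), R²(pH)
and ΔR² = R²(pH+x) − R²(pH) — the variance *x* explains over and above pH —
with standardized β and an F-change test for the increment.

## Worked example

`examples/04_high_expressors.py` simulates a 71/72 case–control cohort with
a planted subpopulation (13% of controls, 32% of cases, displaced 5 core-SD
on the log2 scale), quantifies raw Ct triplicates, and runs the subgroup
procedure. It prints:

```
threshold        = 1.5605 (control median + 1.25*IQR)
flagged          = 25/72 cases vs 5/71 controls
association      chi2(1) = 16.522, p = 0.0000
risk ratio       = 4.93 (odds ratio 7.02)
normal core      = 1.0633 +/- 0.4006 (n = 121, 22 trimmed, KS p = 0.057)
flagged controls sit 8.8 core-SD above the core mean
```

The threshold sits just above the bulk of the control distribution; the
planted case excess is recovered as a significant association and an
elevated risk ratio, and the trimming loop strips the subpopulation before
summarizing the normal core. The other examples cover simulation,
quantification, the comparison battery (which reproduces printed
demographic statistics from summary inputs alone), the regression
decomposition and the full pipeline; each prints a short interpretation.

## Command line

```
ctcohort simulate --seed 1 --outdir sim
ctcohort analyze --config config.yaml
```

`analyze` reads a sample manifest and a long-format Ct table (CSV), and
writes expression, tests, correlations, subgroup, regression and
cleaning-log CSVs plus a run log of every dropped replicate and outlier
flag. Exit codes: 0 ok, 1 validation error, 2 computation error.

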