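# Methods

## Quantification model

Relative quantities use the comparative-Ct (ΔΔCt) method. ΔCt is the target
Ct minus the **geometric mean of the housekeeper Ct values themselves**
(cycle numbers, not linearized 2^−Ct quantities); at least three
housekeepers are required and a missing one is a hard error naming the
gene. ΔΔCt re-centers ΔCt on the arithmetic mean ΔCt of the calibrator
group, computed per gene, so the calibrator group's geometric-mean rq is
exactly 1. The calibrator defaults to the unaffected-control group: no
inter-run calibrator sample is modelled, and amplification efficiencies are
deliberately not corrected for — the pipeline implements plain ΔΔCt, which
assumes near-equal efficiencies between target and reference assays.

**Replicate cleaning.** Technical replicates deviating more than `max_dev`
(default 0.5 Ct, a conventional qPCR repeatability bound) from the
triplicate median are dropped. Pairs are never trimmed: with two values
there is no majority to define which one is aberrant. The median itself
always survives, so at least one replicate remains.

**Population outliers** are flagged by an iterative two-sided Grubbs test
(default α = 0.05) per gene on rq values, using the t-based critical value
G(n, α) = ((n−1)/√n)·√(t²/(n−2+t²)) with t = t₁₋α/(2n), n−2. Constant data
yields no flags (zero SD is treated as "no outliers" rather than an error).
Flags are logged and annotated, never silently removed — which samples to
exclude is an analyst's decision.

## High-expressor subgroup procedure

The threshold T = median + 1.25 × IQR is computed **from controls only**
and applied to all groups. The quartile convention is configurable:
`linear` (interpolation between order statistics; the default in most
scientific software) or `weibull` (the (n+1)p weighted-average hinge used
by SPSS). The two differ slightly in small samples and published cutoffs
cannot adjudicate between them without raw data, hence the option.

The flagged/unflagged × case/control table is tested by Pearson χ² without
continuity correction; prevalence is summarized both as a risk ratio
(case prevalence / control prevalence) and an odds ratio, because "times
more likely" phrasing in the literature is ambiguous between the two.

**Normal core.** The core of the rq distribution is estimated by
reiterative maximum-removal: test the current set with a Kolmogorov–Smirnov
statistic against a normal with estimated mean/SD, using
Lilliefors-corrected significance (plain KS p-values with estimated
parameters are anti-conservative); while p ≤ 0.05 remove the single largest
value (ties: one occurrence per pass, last index — deterministic) and
repeat. The loop stops at p > 0.05 or when removal would leave fewer than
5 values (reported as non-convergence; no minimum core size is standard, 5
keeps the KS test defined). By construction the procedure only ever removes
values at or above the current mean. The default pool is the combined
control+case collection, with a controls-only mode, since published "D(n)"
core sizes do not unambiguously identify which samples entered the
trimming. The flagged subgroup's elevation is (mean(flagged) − core
mean)/core SD, invariant under affine rescaling of the data.

## Comparison battery conventions

- χ² (2×2): Pearson, no Yates correction — validated by exact reproduction
  of published demographic chi-squares (12.437, 16.525) from their integer
  contingency rows. A zero margin is an error, not a zero.
- t tests: equal-variance pooled t (df = n₁+n₂−2), accepting either raw
  vectors or printed (n, mean, SD) summaries so published tables can be
  recomputed directly.
- Mann–Whitney U: smaller-U reporting convention min(U₁, n₁n₂−U₁) as in
  SPSS; exact p (scipy) for tie-free groups of ≤ 20, otherwise the
  tie-corrected normal approximation **without** continuity correction;
  effect size r = |Z|/√N. The uncorrected approximation's distance from the
  exact p is bounded empirically in the tests (< 0.09 for group sizes
  5–8, shrinking with n); it is not accurate to 0.01 at such sizes and no
  variant of the statistic is.
- Tail policy: one-tailed p = p₂/2 only when the observed direction matches
  the pre-specified prediction; on a mismatch the conservative 1 − p₂/2 is
  reported.
- Correlation screen: Spearman (average ranks) by default, Pearson
  optional; pairwise-complete over missing covariates; cells with < 3 pairs
  or a constant member are reported missing rather than dropped silently.
- Two-way ANOVA: fixed effects with interaction, Type II sums of squares
  (statsmodels `anova_lm`) so main effects remain interpretable in
  unbalanced designs; optional Tukey HSD contrasts.
- No multiple-testing correction is applied; reports carry one row per test
  so users can apply their own.

## Regression decomposition

Three OLS fits on z-scored variables: predictor alone, pH alone, pH then
predictor. ΔR² is the step-2 increment; its significance uses the standard
hierarchical F-change test, F = ΔR²/((1−R²_full)/(n−3)) on (1, n−3) df.
β is emitted from **both** the simple and the two-predictor model,
labelled, because published tables do not always state which model a β
belongs to. Missing data are deleted listwise per model and the surviving n
is reported. Perfect collinearity and zero-variance dependents are errors.

## Synthetic-data generator

The generator emulates a two-group postmortem cohort of 71 controls and 72
cases. Covariate defaults: age 47.6 ± 12.2 vs 47.1 ± 12.5 years; tissue pH
6.64 ± 0.28 vs 6.55 ± 0.28; postmortem interval 27.04 ± 12.15 vs
29.89 ± 14.63 h; male proportions 55/71 vs 50/72; left-hemisphere 30/71 vs
37/72; smoking 18/39 vs 46/57 (proportions among donors with recorded
status); suicide 0/71 vs 15/72. Covariates are sampled independently given
group; smoking and suicide are group-conditional Bernoulli because they are
strongly diagnosis-dependent in real collections.

Per gene, log2 expression is core mean + group shift + pH term + N(0, σ_resid),
with a subpopulation indicator (per-group Bernoulli) adding
`subpop_shift_sd` × core SD (default 5). The pH term is linear on the log2
scale with slope and residual SD calibrated analytically so the core's
marginal SD equals `core_sd` and its Pearson correlation with pH equals
`ph_coupling` (default −0.48 for the focal gene; the implied bivariate-
normal Spearman is ≈ −0.46, within a few hundredths). The subpopulation
shift is applied after the pH term, so "5 SD" refers to the core's own
scale. Default focal-gene prevalences are 13% (controls) vs 32% (cases),
matching the high-expressor geometry the pipeline is designed to detect.

Raw Ct triplicates are back-transformed: housekeeper replicates around
fixed baselines (ACTB 18, TBP 27, UBC 22 Ct), target Ct = geomean(baselines)
− log2(rq), replicate noise N(0, 0.15 Ct) — a conventional TaqMan
repeatability figure, not an empirical estimate — and aberrant replicates
displaced ±3 Ct at rate 2% (5% in the cleaning-recovery tests). With zero
noise the quantification chain inverts the generator exactly
(machine-precision round trip). A single integer seed drives cohort,
expression and Ct draws through independent `numpy` Generator streams.

**What the generator does not emulate:** RNA degradation and its Ct drift,
amplification-efficiency differences between assays, plate/batch effects,
medication pharmacology, and any dependence between expression and
covariates other than group and pH. Passing tests therefore demonstrate
that the *procedures* behave correctly under the assumed statistical
structure, not that real tissue data satisfy that structure.

## Numerical notes and known limitations

- The flag rate of the threshold rule on a *pure normal* population is the
  tail beyond median + 1.25·IQR: P(Z > 1.25 × 1.349) ≈ 4.6%. On the
  relative-quantity scale the core is log-normal and right-skewed, so the
  null flag rate is larger (≈ 9% for a 0.5-log2-SD core); consequently the
  observed flagged fraction always exceeds the planted prevalence by that
  null tail, and risk ratios computed from flagged counts are attenuated
  toward 1 relative to the planted prevalence ratio.
- Lilliefors p-values come from statsmodels' table interpolation and are
  clipped at the table bounds; only their position relative to α matters
  here.
- Simulation-based checks use 100–300 replicates at the cohort sizes above
  (n = 143; n = 10,000 for correlation-recovery checks), chosen to keep
  Monte-Carlo error well inside the asserted tolerances.
- Degenerate inputs (constant vectors, zero margins, all-tied ranks,
  zero pooled variance with unequal means) raise typed errors or warning
  states rather than propagating NaNs; tests pin each case.
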