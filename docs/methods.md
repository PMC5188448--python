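# Methods

## Scientific setting

`obgrs` implements an analysis workflow for a question that sits between
genetic epidemiology and risk prediction: does the effect of a type-2
diabetes (T2D) risk variant depend on obesity status, and — if genetic
effects are heterogeneous across obesity strata — should genetic risk
scores (GRS) be built separately for obese and non-obese people?

The motivating setting is a large Mediterranean primary-prevention cohort
of older adults at high cardiovascular risk: roughly 7000 participants,
about half with diabetes at baseline, followed as a staggered open cohort
for incident diabetes (uniform enrollment over ~6.2 years, administrative
censoring 8.7 years after study start, median follow-up ~5.7 years).  The
index variant is the TCF7L2 intronic SNP rs7903146 (C>T, risk allele T,
frequency ~0.374 in this population); nine further T2D SNPs are carried for
the score analyses.

## Statistical models

**Genotype coding.** A call at a biallelic SNP is coded relative to its
declared risk allele: additive (0/1/2 risk alleles), recessive (homozygous
risk vs all other genotypes), or codominant (two indicators against the
homozygous non-risk reference).  Half-calls and other malformed calls are
missing; analyses are complete-case per SNP, mirroring per-analysis n's.

**Quality gate.** Before association analysis, genotype counts are tested
against Hardy–Weinberg proportions with the 1-df Pearson chi-square on
expected counts from the estimated allele frequency.  A monomorphic SNP is
treated as trivially in equilibrium.

**Prevalence models.** Gene–obesity interaction on prevalent T2D is tested
by multivariable logistic regression with genotype contrasts, the obesity
indicator, and their products; the interaction p is a likelihood-ratio test
(LRT) with df equal to the number of genotype contrasts (2 codominant, 1
additive/recessive).  Stratified models give per-stratum ORs with Wald 95%
CIs, plus a per-stratum "global polymorphism" p from the LRT on both
genotype contrasts (the 2-df LRT was chosen where the convention — trend
test vs 2-df — was not fixed; it is labeled as such).  Two adjustment sets
are used: Model 1 (sex, age, field center as indicators) and Model 2
(Model 1 plus energy intake, Mediterranean-diet adherence, alcohol,
smoking, physical activity, dyslipidemia, hypertension).  Fitting is
Newton maximum likelihood (relative tolerance 1e-10, ≤100 iterations) via
statsmodels; perfect separation and rank deficiency raise typed errors
(`SeparationError`, `DesignError` — the latter naming collinear columns).

**Incidence models.** In baseline-diabetes-free subjects, person-years are
summed per genotype×obesity cell and crude rates reported per 1000
person-years.  Cox proportional-hazards models (lifelines, Efron ties,
follow-up time as the time axis, deaths treated as censoring) give
stratified HRs against the homozygous non-risk reference, recessive-model
HRs (TT vs C-carriers), and a pooled interaction LRT on the
genotype×obesity products.  Model 1 here additionally adjusts for the
trial's intervention arm.  Kaplan–Meier curves are exported as
1 − Ŝ(t) step functions with at-risk counts.

**Predictive values.** For the recessive "genetic test" (TT carriage) on
incident T2D: sensitivity, specificity, PPV, and NPV with exact
Clopper–Pearson 95% intervals, and the Pearson chi-square association p for
the 2×2 table, switching to Fisher's exact test when any expected cell is
below 5 (the switch is logged).  The p-value tests association of test and
outcome, not a metric difference between strata, and is labeled so.

**Obesity-specific GRS.** Each candidate SNP is screened by additive
logistic regression against prevalent T2D in the whole sample (adjusted for
age, sex, obesity) and within each obesity stratum (age, sex).  The
partition rule is explicit because published precedent said only
"significant or near-significant": a SNP joins the score of the stratum
with the smaller screening p, provided that p < `alpha_in` (default 0.10,
configurable); otherwise it is excluded with a recorded reason.  Rule,
threshold, screen table, and resulting sets are written to an audit file.
Scores are unweighted risk-allele counts (0..2 per SNP, 0..10 for a
five-SNP set); a subject missing any member genotype gets a missing score —
no prorating.  Score–T2D association is a per-point logistic OR (adjusted
for age, sex, and — in the pooled model — obesity).

**ROC/AUC.** AUC uses the Mann–Whitney rank construction with ties counted
one half; the p-value is the two-sided tie-corrected normal-approximation
Mann–Whitney test of AUC = 0.5.  AUC is computed on the raw integer score
without covariate adjustment, matching score-only ROC curves.  A seeded
percentile bootstrap CI (default 2000 resamples) is available even where
only p-values are conventionally reported.

**BMI trajectories.** The repeated-measures question — does the risk allele
associate with lower BMI, and only in diabetic subjects — involves only
between-subject factors (genotype and baseline diabetes are constant within
subject).  Panels are complete-case over the chosen window (baseline plus
4 or 6 annual visits), so the between-subject stratum of the classical
repeated-measures ANCOVA is algebraically an ANCOVA on per-subject mean
BMI, which is also the exact between-subject test of the
compound-symmetry / random-intercept mixed model for balanced panels.  The
implementation therefore fits OLS on subject means and reports exact
F-tests for the genotype effect and the genotype×T2D interaction — chosen
over an iterative mixed-model fit because it is exact, fast, and identical
for complete balanced panels (tests verify the equivalence against the
two-sample t-test on subject means).  Adjusted means per
genotype×T2D×visit are per-visit OLS predictions at covariate means.

## Synthetic cohorts

The generator draws, in order: independent HWE genotypes at the ten SNPs;
covariates (age ~ N(67, 6.2) clipped to 55–80, 57.4% female, centers,
1:1:1 intervention arms, energy/adherence/alcohol/activity/smoking and
comorbidity indicators matched to the cohort's descriptive table, generated
independently of genotype); baseline BMI ~ N(29.7, 3.8) with the location
set so that P(BMI ≥ 30) equals the 46.7% obesity target; obesity as
BMI ≥ 30; prevalent T2D from an obesity-stratified logistic model whose
intercepts are calibrated by root-finding to per-stratum prevalence targets
(49.1% non-obese, 48.4% obese) and whose genotype ORs default to the
published stratified pattern (index SNP CT/TT 1.78/2.26 non-obese,
1.27/1.53 obese; background SNPs per-allele 1.15 confined to their score's
stratum); a −0.5 kg/m² per-risk-allele BMI shift confined to diabetic
subjects (applied after T2D assignment, with obesity then recomputed from
final BMI so the BMI ≥ 30 invariant always holds); and, for
prevalence-free subjects, exponential event times with stratum-specific
baseline hazards (11.6 and 17.7 per 1000 PY in homozygous non-risk
non-obese/obese subjects) times stratified genotype HRs (1.14/1.81
non-obese, 1.05/1.01 obese), uniform entry over the 6.2-year accrual
window, and administrative censoring at 8.7 years — which reproduces the
~5.6-year median follow-up and ~312 expected events.  A helper calibrates
the baseline hazard scale to any target event count by solving
E[events] = Σ n·w·(1 − E[e^(−λC)]) with C uniform on [2.5, 8.7].

Background-SNP risk-allele frequencies (0.11–0.47) are typical European
values for these loci.  Loci are simulated without linkage disequilibrium,
covariates without genotype confounding, and censoring is purely
administrative (last-visit dropout is not modeled) — so passing recovery
tests demonstrate correctness of the estimators under the assumed
structure, not robustness to LD, confounding, or informative censoring in
real data.

The annual BMI panel adds a population drift (−0.05 kg/m²/year), optional
per-allele slope effects by diabetes status, and within-subject noise
(SD 0.8 kg/m²) around the genotype-shifted baseline.

All draws flow through a single `numpy.random.Generator`; the same seed
yields byte-identical cohorts.

## Monte-Carlo power

`estimate_power` simulates the longitudinal design directly: n = 3607
diabetes-free subjects, TT carrier frequency 11.8%, obesity prevalence 47%,
stratum baseline hazards in the observed 1.5:1 obese:non-obese ratio scaled
so expected events ≈ 312, and a carrier hazard ratio confined to non-obese
subjects so that the carrier×obesity interaction ratio equals the requested
effect (1.75 by default — the observed pattern of effect confinement).
Each replicate is tested with the 1-df Cox LRT on the product term;
detection fractions carry exact binomial CIs, and replicate-level fit
failures are excluded from the denominator only if below 5%.

Under these conditions the measured power at an interaction ratio of 1.75
is ~40–45%, consistent with the analytic approximation
Var(β̂_int) ≈ Σ 1/d over the four carrier×obesity event counts
(≈ 26, 113, 21, 152 → SE ≈ 0.32, z = ln 1.75 / 0.32 ≈ 1.76).  A claim of
≥80% power at this design is reachable only if the 1.75 is interpreted as a
stratum-specific main effect detectable with 312 events rather than as the
product-term ratio; the package reports what the stated test actually
delivers.

## Problem sizes and numerical choices

Simulation-based tests use 120–200 replicates at the cohort sizes the
analyses target (n = 7018 for prevalence, 3607 for incidence, 1000 for the
score subsample), with smaller n for pure calibration checks; these sizes
were chosen so the whole suite runs in minutes while keeping Monte-Carlo
error well below the margins being asserted.  Wald CIs use z = 1.959964;
LRT statistics are floored at 0 against round-off; logistic fits reject
|β| > 25 as separation; rank checks use `numpy.linalg.matrix_rank` on
centered designs.  Percentages and rates are reported to 1 decimal and
ORs/HRs/AUCs to 2–3 decimals in the exported tables.

## Known limitations

- Apparent (in-sample) AUC only; no cross-validation or shrinkage of the
  score partition, so stratum-specific AUC estimates are optimistic.
- The screen/partition procedure inherits winner's-curse bias at pilot
  sample sizes; at n = 1000 with per-allele ORs of 1.15 individual SNPs
  frequently miss the 0.10 entry threshold.
- No competing risks, time-varying covariates, LD, population structure,
  or informative censoring.
- Proportional-hazards diagnostics are limited to lifelines' built-in
  checks; no formal Schoenfeld test is exported.
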