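# obgrs

Gene–obesity interaction analysis and obesity-specific genetic risk scores
(GRS) for type-2 diabetes (T2D) cohorts.

## The problem

The TCF7L2 rs7903146 C>T variant is the strongest common genetic risk
factor for T2D, but its effect is not homogeneous: in several populations
the association is markedly stronger in non-obese than in obese people.
If genetic effects differ by obesity status, a conventional GRS — an
unweighted count of risk alleles pooled across SNPs chosen from
unstratified GWAS — dilutes stratum-specific signal.  `obgrs` implements
the full analysis workflow for this question on subject-level cohort data:

- genotype coding (additive / recessive / codominant), genotype
  frequencies, and the Hardy–Weinberg quality gate;
- obesity-stratified logistic models for prevalent T2D with
  likelihood-ratio gene×obesity interaction tests, and linear models for
  BMI and related traits with gene×T2D interactions;
- person-years, crude incidence rates, stratified Cox models with
  interaction tests, and Kaplan–Meier 1 − S(t) exports for incident T2D;
- sensitivity/specificity/PPV/NPV of the recessive "genetic test" by
  stratum, with exact CIs;
- **obesity-specific GRS**: per-stratum SNP screening, an explicit
  partition rule (a SNP joins the score of the stratum where its
  association is stronger, given p < 0.10), unweighted 0–10 scoring, and
  stratum-specific ROC/AUC by the Mann–Whitney construction;
- repeated-measures BMI trajectory analysis (genotype×T2D between-subject
  tests);
- a synthetic-cohort generator with the matching statistical structure
  (HWE genotypes, ~47% obesity, ~49% prevalent T2D, stratified ORs and
  HRs, staggered open-cohort follow-up) and Monte-Carlo power estimation.

For one SNP with risk allele dosage g ∈ {0,1,2} and obesity indicator E,
the central prevalence model is

    logit P(T2D = 1) = β₀ + β₁·I(g=1) + β₂·I(g=2) + γ·E
                       + δ₁·I(g=1)·E + δ₂·I(g=2)·E + covariates,

with the interaction tested by the 2-df likelihood ratio on (δ₁, δ₂); the
incidence analogue replaces the logit with a Cox partial likelihood.  A
five-SNP obesity-specific score is S = Σ gⱼ ∈ {0,…,10}, and its predictive
value in stratum E is AUC(S | E) = P(S_case > S_control | E) + ½·P(ties).

See `docs/methods.md` for models, calibration, and design choices.

## Worked example

```python
import obgrs
from obgrs.simulate import SimulationConfig, simulate_cohort

cohort = simulate_cohort(SimulationConfig(), seed=1)   # n = 7018

counts = obgrs.genotype_counts(cohort, "rs7903146")
chi2, p = obgrs.hwe_test(counts)

for r in obgrs.stratified_or(cohort, "rs7903146", model="Model2"):
    print(f"{r.stratum:9s} {r.contrast}: OR {r.or_value:.2f} "
          f"({r.ci_low:.2f}-{r.ci_high:.2f}), p = {r.p_value:.2g}")

res, p_int = obgrs.cox_stratified_and_interaction(cohort, "rs7903146")
```

prints (seed 1):

```
non-obese CT vs CC: OR 1.92 (1.67-2.21), p = 6.3e-20
non-obese TT vs CC: OR 2.85 (2.33-3.47), p = 6.8e-25
obese     CT vs CC: OR 1.15 (0.99-1.34), p = 0.075
obese     TT vs CC: OR 1.44 (1.15-1.80), p = 0.0013
```

The TT odds ratio is about twice as large in non-obese as in obese
subjects — the generator's built-in effect heterogeneity, which the
stratified fit recovers; the gene×obesity interaction p for this draw is
< 1e-4.  The incidence side of the same draw gives, for example, non-obese
TT: 24 cases over 1082.8 person-years (crude rate 22.2/1000 PY), HR 1.85
(1.15–2.97) vs CC, against HR 1.30 (0.83–2.04) in obese TT.

The same pipeline runs from the shell, from a simulated or a real cohort
CSV (plus optional VCF genotypes):

```bash
obgrs --seed 1 --out-dir out all           # simulate + every analysis stage
obgrs --seed 1 --out-dir out grs --cohort my_cohort.csv --annotations snps.csv
```

writing tidy TSV/JSON tables (stratified ORs, incidence cells, ROC curves,
GRS partition audit, BMI trajectories) and a reproducibility manifest.

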