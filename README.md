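# riskstrat

Risk stratification of clinical cohorts by a continuous plasma biomarker.
The package grew out of the question of whether extracellular NAPRT
(eNAPRT, an NAD-biosynthetic enzyme released by stressed cells and acting
as a damage-associated molecular pattern) predicts mortality in sepsis, but
every stage is generic: give it one row per subject with biomarker
concentrations, a binary outcome and optional survival columns, and it will

- **scan every candidate cut-off** of the biomarker, building a 2×2
  confusion matrix (exposure `x ≥ τ` × outcome) per threshold with a
  two-sided Fisher exact p, a Pearson χ² p and a risk ratio with a 95% Katz
  confidence interval, then select the best cut-off by minimum Fisher p
  (Bonferroni/Holm adjustment reported alongside);
- **compare survival** of the dichotomized groups with the Kaplan–Meier
  product-limit estimator and the two-group log-rank test;
- **search for biomarker interactors** with a genetic algorithm over
  binomial-GLM effect subsets (main effects + pairwise interactions under
  the marginality constraint), ranked by BIC = −2 ℓ + k ln n and validated
  against an exhaustive enumeration oracle;
- **summarize gene-signature overlaps** (Venn arithmetic on ID lists); and
- **simulate calibrated synthetic cohorts** — log-normal marginals, a
  Gaussian copula linking CRP to the primary biomarker, and a step
  change-point mortality model — so the whole pipeline is testable without
  patient data.

## The statistics in brief

For a threshold τ the cohort splits into `high = {x ≥ τ}` and
`low = {x < τ}` (ties go high). With cells a,b,c,d (events/non-events by
group), the scan records

- Fisher's exact test: two-sided by the minimum-likelihood rule — the sum
  of hypergeometric point probabilities ≤ that of the observed table with
  margins fixed;
- risk ratio RR = [a/(a+b)]/[c/(c+d)] with
  CI = exp(ln RR ± z·√(1/a − 1/(a+b) + 1/c − 1/(c+d))), Haldane–Anscombe
  +0.5 correction (flagged) when an event cell is zero;
- Pearson χ² (uncorrected by default; Yates optional).

Survival uses the standard aggregated-ties log-rank statistic
(O₁ − E₁)²/V with hypergeometric variance. Model selection fits logistic
regressions by IRLS and lets a seeded GA (population 50, 100 generations,
tournament selection, uniform crossover, bit-flip mutation, elitism, and a
repair operator enforcing marginality) minimize BIC.

## Worked example

```
$ riskstrat run --n 100 --seed 17
riskstrat v0.1.0 (seed=17)
cohort: n=100, events=39
best cut-off: tau=14.2  matrix=(36,41,3,20)  fisher_p=0.00348
  mortality >= tau: 46.8%   < tau: 13.0%   RR=3.58 [1.22, 10.6]
log-rank: chi2=7.51 p=0.00615
best model: eNAPRT + CRP + Plts + eNAPRT:CRP + eNAPRT:Plts  BIC=126.45
```

This simulates a 100-patient septic cohort from the calibrated generator
(median eNAPRT 27.1 ng/ml, 71% of patients at or above the 15 ng/ml
change-point, death probabilities 0.44 above / 0.10 below), scans all
admissible cut-offs and lands near the planted change-point (14.2 ng/ml
here; sampling noise at n=100 moves it by a few ng/ml), reports the
confusion matrix and group mortality at that cut-off, confirms the survival
split by log-rank, and runs the GA model search over the routine covariates
(CRP, PCT, WBC, Plts, INR, eNAMPT) and their interactions with eNAPRT.

Individual stages are also available as subcommands (`simulate`, `scan`,
`survival`, `select-model`, `overlap`) and as plain library functions; see
`docs/methods.md` for the statistical conventions and generator
calibration.

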