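# Methods

This note records the statistical conventions, generator calibration and
design choices behind `riskstrat`, in the spirit of a model-description
appendix: what each stage computes, which knobs matter, and what the
synthetic cohorts do and do not emulate.

## Cohort model

One row per subject: unique id, named nonnegative biomarker concentrations
(missing allowed, never imputed), binary outcome (1 = died), optional
right-censored survival (`time` in days with an `event` indicator; the two
must appear together). Units are metadata only — the covariates mix ng/ml,
mg/l, mg/dl and U/l and no conversion is attempted. Summaries report the
median (midpoint of the central order statistics) and the IQR with
linearly interpolated quartiles; these conventions are stated because
"median ± x" summaries in clinical reports are otherwise ambiguous.

Dichotomization at τ puts ties in the high group (`x ≥ τ`), matching the
clinical convention of defining the exposed group as "biomarker ≥ cut-off".
Subjects with a missing biomarker value are excluded from the split and
counted, so `|high| + |low| + n_missing = n` always holds.

## Threshold scan

Candidate cut-offs are the sorted unique observed values whose `≥ τ` split
leaves both groups at or above `min_group_size` (default 5; configurable
down to 1 for toy examples). Observed values rather than midpoints make the
grid exhaustive and deterministic under the `≥` rule; no rounding or
binning of concentrations is performed.

Per candidate the scan stores the 2×2 matrix, the two-sided Fisher exact p,
the uncorrected Pearson χ² p and the risk ratio with 95% CI. The best
cut-off minimizes the **raw** Fisher p among non-degenerate records, with
ties broken by larger |ln RR| and then by smaller τ. Minimum-p selection
over many candidate splits is optimistic (the maximally-selected-statistic
problem); the ledger therefore carries Bonferroni or Holm adjusted p-values
(via statsmodels) for honesty, but the adjustment never drives selection.
No ROC/AUC machinery or cross-validated cut-point tuning is provided — the
procedure implemented is the exhaustive Fisher-validated scan.

## 2×2 statistics

- **Fisher exact, two-sided**: minimum-likelihood rule — sum all
  hypergeometric point probabilities (margins fixed) not exceeding the
  observed one. Point probabilities are compared with a 1e-7 relative
  tolerance to absorb floating-point rounding; the test suite validates the
  result against an exact-integer enumeration oracle for every table with
  n ≤ 40. Zero-margin tables return p = 1 and are flagged degenerate.
- **Pearson χ²**: Σ(O−E)²/E on 1 df, uncorrected by default. The Yates
  continuity correction is available but off: on the reference table
  (31,40,3,26) the uncorrected statistic gives p ≈ 0.0014, consistent with
  the χ² p of 0.001 reported for that dichotomy, while the corrected one
  (≈0.003) is not.
- **Risk ratio**: Katz log-method CI. **Odds ratio**: Woolf log CI. A zero
  event cell (RR: a or c; OR: any cell) triggers the Haldane–Anscombe +0.5
  added to all four cells, with a `corrected` flag rather than a failure,
  because threshold scans routinely traverse extreme cut-offs.
- Confidence level defaults to 95% (z = Φ⁻¹(0.975)).

## Survival

Kaplan–Meier product-limit estimates per group; censored-only times reduce
the risk set without stepping S(t). The log-rank test aggregates ties:
at each distinct event time t_j with d_j events, E and the hypergeometric
variance d_j(n_j−d_j)n_{1j}n_{2j}/(n_j²(n_j−1)) accumulate, and the
statistic (O₁−E₁)²/V is referred to χ²₁. Subjects censored at an event
time are counted at risk there (event before censoring). No Cox models,
Greenwood intervals or weighted log-rank variants.

## GLM model selection

Logistic regressions are fitted by IRLS (statsmodels GLM, binomial family,
tolerance 1e-8, 100 iterations); concentration covariates enter as natural
logs. BIC = −2·loglik + k·ln n with natural log and k counting the
intercept — pinned so scores are exactly reproducible. Separation is
flagged when a standardized coefficient exceeds 15; rank-deficient designs
raise an error naming the dependent columns. Nested models are compared by
analysis of deviance (χ² on the deviance difference).

The candidate space defaults to the seven main effects (eNAPRT, CRP, PCT,
WBC, Plts, INR, eNAMPT) plus the six pairwise interactions involving
eNAPRT (the scientific question being which covariates modify the primary
biomarker's effect); all pairwise interactions are available by option.
The marginality constraint — an interaction only alongside both its mains —
is enforced at construction and restored by a repair operator after every
GA variation step, standard practice for hierarchical interaction models.

GA defaults: population 50, 100 generations, tournament selection (k = 3),
uniform crossover with probability 0.9, per-bit mutation 1/L, elitism 2,
mandatory integer seed. The initial population always contains the
intercept-only and the repaired full chromosome, so the best BIC can never
be worse than either. Fitness evaluations are memoized per inclusion
vector, which also makes GA-vs-exhaustive-oracle equality checks cheap for
small candidate spaces. BIC (not AIC) is the ranking criterion because it
penalizes the many near-equivalent interaction models more sternly.
Model fitting is complete-case; no imputation.

## Synthetic cohort generator

The generator exists so that every downstream stage has realistic,
seed-reproducible input. It emulates a septic cohort with these defaults:

- **eNAPRT**: log-normal with median 27.1 ng/ml and log-scale
  σ = (ln 27.1 − ln 15)/Φ⁻¹(0.71) ≈ 1.07, i.e. calibrated so that 71% of
  subjects fall at or above the 15 ng/ml change-point. Log-normal marginals
  are used for all concentration variables (strictly positive,
  right-skewed); where no calibration constraint applies σ defaults to 0.6
  (0.8 for PCT, 0.4 for WBC and platelets, 0.2 for INR — wider for
  acute-phase analytes, narrow for INR which is tightly regulated).
- **Mortality**: a step change-point model, P(death) = 0.44 if
  eNAPRT ≥ 15 ng/ml else 0.10 — exactly the dichotomized mortality the
  scan is designed to recover. The implied overall death rate is
  0.71·0.44 + 0.29·0.10 = 0.341. A smooth logistic mode exists for power
  studies but is not the default.
- **Survival**: deaths draw times uniformly in (0, 28] days; survivors are
  censored at day 28 (a common sepsis-trial follow-up). Only the ordering
  structure matters to the KM/log-rank stage.
- **Covariates**: CRP, creatinine and LDH have group-conditional medians
  (209/130 mg/l, 1.8/1.1 mg/dl, 488/392 U/l for the ≥15 / <15 groups), so
  group-comparison checks reproduce the expected direction of effects. CRP
  is additionally tied to eNAPRT's latent Gaussian with copula correlation
  ρ = 0.325, fixed once by the package's bisection calibrator
  (`tune_rho_for_pearson`) so the raw-scale Pearson correlation is ≈0.31
  at Monte-Carlo scale. eNAMPT (median 5.05 ng/ml), PCT (2.0 ng/ml), WBC
  (12×10⁹/l), Plts (200×10⁹/l) and INR (1.3) are independent log-normals
  at typical sepsis values.
- **Determinism**: one integer seed; each variable and the outcome stage
  draw from sub-streams derived via `SeedSequence(seed, index)`, so output
  is bit-identical for identical (config, seed).

What the generator does **not** emulate: time-varying biomarkers,
treatment effects, competing risks, measurement error or informative
censoring, heavy-tailed contamination, or the real joint dependence of the
clinical covariates beyond the single CRP copula and the group-conditional
medians. Distributional forms and dispersions are generator policy, not
estimates from data — the source cohort was never deposited — so passing
tests demonstrate internal consistency of the pipeline under a plausible
data-generating process, not agreement with any real cohort's microdata.

## Numerical choices and degenerate inputs

- Fisher tie tolerance 1e-7 (relative) on point probabilities.
- p-values floored at the smallest positive double; never exactly 0.
- Zero-margin tables: Fisher returns 1 with a degenerate flag; χ² raises.
- All-missing biomarkers, constant sequences, all-same outcomes, empty
  exposure rows, non-nested model pairs and rank-deficient designs raise
  typed errors early rather than propagating NaNs.
- Scan thresholds are compared on exact stored float values.

## Problem sizes used in the test and acceptance runs

Monte-Carlo calibration checks use 2×10⁵ subjects; change-point recovery
and permuted-outcome null controls use 200 replicate cohorts of n = 100;
GA-vs-oracle equivalence uses 20 seeded cohorts of n = 200 over a 7-effect
candidate space; the acceptance script recovers the cut-off as the median
over 15 cohorts of n = 1000, where the scan's selection concentrates
tightly around the planted change-point. These sizes give comfortable
Monte-Carlo margins for every tolerance asserted.

## Known limitations

- Minimum-p cut-off selection is optimistic by construction; the adjusted
  p-values quantify but do not remove this.
- The recovery of a planted change-point at n = 100 has a heavy right
  tail: above the change-point the high group remains pure while the low
  group dilutes slowly, so the Fisher-p landscape is shallow on that side
  and the selected cut-off occasionally lands well above the truth
  (roughly one cohort in eight at the default settings). At n = 1000 the
  selection is tight.
- The GA guarantees nothing beyond its seeds and elitism on large
  candidate spaces; the exhaustive oracle is the ground truth only up to
  15 effects.
- One-biomarker-at-a-time scans; no stratified (Mantel–Haenszel) or r×c
  contingency generalizations.
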