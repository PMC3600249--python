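# Methods

## The scoring model

`cbcscore` implements a prognostic scoring system for critically ill
patients built from the complete blood cell count (CBC).  Five parameters
enter: absolute neutrophil count (Neu), absolute lymphocyte count (Lym),
red cell count (RBC), hemoglobin (HB), and platelet count (Plt).

Each measurement *X* is standardized against a healthy-population
reference range (mean X̄, standard deviation S) into a **directionally
signed Z-value**:

* Neu, Lym (elevated in critical illness): Z = (X − X̄)/S
* RBC, HB, Plt (depressed in critical illness): Z = (X̄ − X)/S

so that positive Z always points toward death risk.  The **prognostic
score** of a patient is the **median** of the Z-values over the selected
parameter set.  The median rewards *concerted* deviation across
parameters: a single extreme value cannot dominate, so the score reads as
a quantitative summary of holistic physiological change.  A healthy
subject has every Z near zero and a score of exactly zero — the
theoretical anchor the tests assert.

Predictors are chosen by **Spearman rank correlation** between survival
time (whole days from CBC sampling to death) and each parameter,
two-tailed at α = 0.05.  On the study cohort this selects Neu and Lym
(negative correlation with survival) and Plt (positive), which is the
package's fixed default scored set {NEU, LYM, PLT}; `select="auto"`
re-runs the selection on the cohort at hand.

### Assumptions

* Every subject died within 365 days of sampling (inclusion criterion);
  there is no censoring, so no survival-model machinery (Kaplan–Meier,
  Cox) appears anywhere.
* The reference ranges are taken as given constants; no age/sex
  stratification or between-laboratory unit conversion.
* The score is a cross-sectional snapshot of the CBC at one sampling
  time; serial measurements are out of scope.

## Key parameters and defaults

| parameter | default | meaning |
|---|---|---|
| reference panel | Neu 3.5±1.2, Lym 2.2±0.6 (10⁹/L); RBC 4.5±0.6 (10¹²/L); HB 142±20 (g/L); Plt 210±53 (10⁹/L) | standardization constants; directions high-is-risk for Neu/Lym, low-is-risk for the rest |
| `alpha` | 0.05 | two-tailed significance level for selection |
| selected set | {NEU, LYM, PLT} | the predictors significant on the study cohort |
| `require_complete` | False | score over present selected parameters (≥ 1); True demands all present |
| `missingness_rate` | 0.0 | per-value blanking probability in the simulator |
| `value_floor` | 0.01 | lower truncation of simulated CBC values |

Survival groups: Day 1…Day 5 singly, then Days 6–30, Days 31–180,
Days 181–365 — an exact partition of [1, 365].  (Equivalent published
descriptions disagree by one day on the last boundary; [181, 365] is the
self-consistent choice that keeps the partition disjoint.)

## Statistical and numerical choices

* **Median convention.** Even numbers of contributing Z-values (possible
  only with missing data or a non-default selection) take the mean of the
  two central order statistics.
* **Spearman with midranks.** Rho is the Pearson correlation of midrank
  vectors (average ranks on ties), the standard convention.  Undefined
  correlations (a constant vector) raise rather than returning 0.
* **p-values.** Two-tailed via t = ρ·√((n−2)/(1−ρ²)) on n−2 degrees of
  freedom; |ρ| = 1 returns p = 0 by convention.  An exact-permutation
  enumeration (n ≤ 10) serves as independent oracle: the t-approximation
  agrees with exact enumeration within **0.10 absolute** for 5 ≤ n ≤ 8
  (measured maxima 0.077 at n = 5 shrinking to 0.024 at n = 8), and far
  better at cohort sizes in the hundreds where it is actually used.
* **Missing data.** Pairwise-complete deletion per parameter in
  selection; fewer than 4 complete pairs → flagged untestable, never
  silently selected.  Scoring uses present selected parameters; a record
  with none is reported *unscorable*, never given a silent zero (zero is
  a meaningful score).
* **Quantiles.** Linear interpolation between order statistics at
  h = p·(n−1) (numpy's `linear` method), fixed because quartile
  conventions genuinely differ at the small group sizes here (n = 21–64).
* **Group SDs** use the sample (n−1) denominator.
* Measurements of exactly 0 are legal score inputs; no floor is applied
  at scoring time (the floor exists only in the simulator).

## The synthetic cohort generator

No patient-level data is distributed, so the generator reproduces the
*published group structure*: eight survival groups of sizes
59, 64, 29, 21, 34, 38, 37, 24 (total 306), each with its published
per-parameter mean ± SD.  Within a group each CBC value is an
**independent normal draw, rejection-truncated below at 0.01** —
rejection rather than clamping, so no point mass at the floor distorts
the means.  Several group SDs approach their means (e.g. Lym 2.1 ± 1.9),
so truncation is unavoidable; `empirical_check` measures the resulting
bias, and the moment-recovery test asserts mean recovery only for RBC and
HB, whose group means sit > 2.9 SD above the floor.

Survival times: the fixed day for Day 1–Day 5; uniform integers over the
day range for the interval groups.  A `median_matched_group_specs()`
preset instead draws half the mass uniformly from [lo, m] and half from
[m+1, hi], placing each interval group's median on the observed values
(14, 91, 296) — a plain symmetric uniform cannot reach 296 inside
[181, 365].

**What the generator does not emulate:** cross-parameter covariance
within a group (Table-style sources report only marginals) and any
within-group association between CBC values and survival day.
Consequently cohort-level correlations arise purely from between-group
mean shifts and are *stronger* than those observed in real data
(simulated ρ(NEU) ≈ −0.35 vs −0.14 observed).  Passing tests therefore
demonstrate the pipeline's correctness and the *signs* and group-level
contrasts of the published analysis — not the published correlation or
quartile magnitudes, which depend on the real data's unreported joint
structure.

## Design choices that were genuinely open

* Risk direction is a property of the `ReferenceRange`, not baked into
  the formula, so the machinery generalizes to other panels; the bundled
  panel pins the published directions.
* The scored set is explicit everywhere (the published methods text reads
  as "all measured parameters", the published analysis uses the three
  significant ones); the default is the three-parameter set, with
  `--select-auto` / `select="auto"` and `--parameters` to change it.
* Survival time enters selection as exact days, not group index — group
  medians are a reporting device, not the analysis variable.
* No multiple-testing correction across the five parameters, matching
  the original analysis; with five tests at α = 0.05 this is a conscious
  reproduction choice, not an oversight.

## Problem sizes

Tests and the acceptance checks run cohorts of n = 306 (20 replicates for
the sign-recovery and group-contrast properties), 100× inflated groups
for moment recovery, all 720 permutations of n = 6 for the rank-
correlation oracle, and ≥ 1000 randomized instances for the median and
quantile invariants.  The full suite completes in well under a minute.

## Known limitations

* The score is validated here against synthetic cohorts only; the
  generator's independence assumptions make real-data magnitudes
  unreachable by construction (see above).
* Reference ranges are single-laboratory constants; portability across
  analyzers or populations is untested.
* The t-approximation p-value is conservative/anticonservative by up to
  0.08 at n ≤ 5; use `spearman_p_exact` for tiny samples.
* Whole-day survival resolution; same-day death is day 1.
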