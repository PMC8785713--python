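# Methods

This note documents the models, calibrations and numerical choices behind
`taigrade`, and what the synthetic experiments do and do not establish.

## Lesion vocabulary

A lesion observation is a tuple (region, subregion, laterality, sequence
family). Seven regions are recognised — basal ganglia, corpus callosum
(trunk / splenium / genu-rostrum), posterior limb of the internal capsule,
midbrain (tegmentum / tectum / cerebral peduncles / unspecified), pons
(ventral / dorsal / unspecified), subcortical white matter, thalamus — and
three sequence families (DWI, FLAIR, susceptibility-sensitive = SWI with
T2\*GRE as its historical equivalent). The corpus callosum is midline, so
its laterality is fixed at `not_applicable`. TAI is present/absent only;
lesion volume is out of scope. The full catalog is 75 sites.

The substantia nigra is not a separate value: anatomically it lies in the
midbrain tegmentum, and the tegmentum compartment carries its grading role.

## Grading engines

All four systems are implemented as ordered rule ladders evaluated from the
most severe grade down, across all sequence families, so a map earns the
highest grade any of its sites supports (most-severe-grade precedence).
Interpretation choices that the printed rules leave open:

* **Abu Hamdeh grade III** excludes tegmental midbrain lesions on *any*
  sequence (its own footnote); a tegmentum lesion seen only on DWI/FLAIR
  therefore yields neither grade IV (wrong family) nor grade III.
* **Age exactly 30** falls in Abu Hamdeh stratum b (the rules print "<30"
  and ">30", leaving 30 unassigned).
* **Firsching on an empty map** returns 0, not I: "supratentorial lesions
  only" presupposes at least one lesion. Stockholm has no grade 0 — grade I
  absorbs lesion-free patients and lesions in unlisted regions.
* **Firsching laterality** is assessed per region: co-occurring unilateral
  midbrain and unilateral pontine lesions are unilateral brainstem
  involvement (grade II), not a bilateral pattern.
* Pons ventral/dorsal subregions are ignored by every grading rule (only
  laterality matters); they are retained for the severity table.

Every engine is checked against an independent declarative rule-table
interpreter on exhaustive one- and two-site maps and 10,000 random maps,
and all four are monotone under lesion addition.

## Synthetic cohort generator

The generator emulates a single-centre neurointensive-care TBI cohort of
adults scanned within 28 days of injury. One latent severity scalar
`z ~ N(0, 1)` drives everything:

* **Lesions.** Each site s has `P(s | z) = expit(c_s + b·z)` with slope
  `b = 1.6`. The intercepts are solved by Gauss-Hermite quadrature so each
  site's marginal prevalence matches a target table of per-site rates (351
  patients' worth of per-lesion-type counts; midbrain/pons subregion rows
  carry no laterality and are split 70/30 unilateral/bilateral, which is our
  construction). A single global intercept shift is then solved so that the
  probability of at least one *observed* lesion equals 73%.
* **Detectability decay.** Observed lesions are a thinning of true lesions:
  a site survives with probability `m_seq^delay`, with daily retention
  multipliers 0.955 (DWI), 0.975 (FLAIR), 0.995 (susceptibility), encoding
  that non-hemorrhagic TAI fade from MRI with time while hemorrhagic traces
  persist. Grading and outcome use the observed map.
* **Covariates.** Marginals are exact via Gaussian-copula coupling: a
  coupled percentile is pushed through each covariate's quantile function.
  GCS (median 4, IQR 3–7, range 3–15) couples at −1.3 (severe injury, low
  GCS), pupillary status (69/10/19% responsive/unilateral/bilateral) at
  +1.0, Rotterdam CT score at +1.0, and age weakly at +0.5 — age is a core
  prognostic variable in TBI and the weak coupling both makes it prognostic
  and gives chained imputation signal to exploit. Age is truncated-normal on
  [15, 82] with underlying location/scale solved so the truncated mean and
  SD are 43.8 and 18.6. Scan delay is lognormal (median 7 d, Q3 13 d)
  truncated to 0–28 days.
* **Outcome.** Unfavorable outcome (GOS 1–3) is Bernoulli conditional on
  the Stockholm grade of the observed map: 0.28 / 0.40 / 0.74 / 0.97 for
  grades I–IV. The 5-level GOS splits the halves 38:9:136 (GOS 1:2:3) and
  106:62 (GOS 4:5). The slope `b = 1.6` was fixed by scanning for the value
  at which the implied grade mixture reproduces the reference cohort's
  overall unfavorable fraction of 52.1% (183/351); it was then frozen.

All randomness flows from one seed through named substreams
(`numpy.random.SeedSequence.spawn`), so identical configurations generate
identical cohorts.

**What the generator does not emulate.** Lesion co-occurrence beyond a
single latent factor (no region-specific correlation structure), any direct
effect of individual lesion sites on outcome conditional on grade, selection
into MRI referral, informative missingness, or inter-rater variability in
lesion annotation. Consequently, tests that pass on synthetic cohorts
establish that the pipeline's machinery is correct and that the generator
meets its calibration targets — not that any grading system has a
particular performance in real patients.

## Missingness and imputation

Missingness is injected completely at random over the four covariate cells
(age, GCS, pupils, Rotterdam) at a default 4% rate; outcome and lesion data
are never masked. `impute_chained` cycles regression equations (multinomial
logistic for pupillary status, linear with range clipping and integer
rounding for the rest, the dichotomized outcome included as a predictor) for
10 iterations from a random-draw initialization. Imputations are the
regression *predictions*, not posterior draws: the completed data feed point
prediction, where the conditional mean is the right imputation; posterior
draws would add irreducible noise (mean absolute error inflated by roughly
sqrt(2(1−R²))) without any downstream benefit here.

## Derivation pipeline

The 2/3:1/3 split is stratified by outcome with largest-remainder per-class
quotas (|train| = round(2n/3) exactly). The GA is generational: population
50, 40 generations, tournament size 3, uniform crossover at 0.8, per-bit
mutation 1/L, elitism 2, all config-exposed. The initial population always
contains the empty and all-features chromosomes, so the best-ever result is
bounded below by both. Fitness is the desirability
`sqrt(d_auc · exp(−λk))` of the subset's 5-fold stratified
cross-validated logistic AUC, with λ = 0.1; logistic fitness (rather than
refitting the forest per generation) keeps selection cheap and separates
selection from validation. Fitness evaluations are cached by chromosome, and
elitism makes the best-fitness trace non-decreasing by construction.
Candidate features are the 60 (lesion type × sequence) indicators. A
`force_include` option lets judgment-based additions (e.g. thalamic TAI)
bypass the GA.

Random-forest validation trains scikit-learn forests (500 trees by default)
on core variables ± selected features and compares test-set AUCs; variable
importance is mean decrease in Gini impurity.

## Evaluation battery

* Logistic models are ML fits (statsmodels). Grading systems enter as a
  single ordinal integer (0/1–4) — each system is one added predictor and
  the grades form an escalating scale; pupillary status enters as a 3-level
  categorical (two indicators). Perfect separation or non-convergence
  triggers a warning and a ridge-penalized fallback whose log-likelihood is
  computed from its fitted probabilities.
* AUC is the Mann-Whitney estimator with half-credit ties.
* Nagelkerke pseudo-R² rescales Cox-Snell by its maximum `1 − exp(2·ll0/n)`.
* The DeLong test uses midrank placements; its single-curve variance agrees
  with the Hanley-McNeil formula (U-statistic plug-ins for Q1/Q2) — an
  asymptotic identity, verified numerically at ~1000 patients per class.
  Degenerate variance (identical curves) returns p = 1 with a warning.
* The likelihood-ratio test requires properly nested predictor sets on the
  same patients; its type-I error is verified by simulation at α = 0.05.
* Cochran-Armitage uses the standard trend statistic with a two-sided
  normal p-value, checked against a permutation oracle.
* `compare_grading_systems` fits the 15 benchmark models (core; Rotterdam;
  each system alone; core+system; core+Rotterdam+system), runs the LRT of
  each system's addition to both baselines, and the pairwise DeLong tests
  among the four univariate system models (on the univariate models'
  fitted probabilities; a config point left open deliberately, as the
  multivariate alternative is a one-line change). Two-sided tests
  throughout; no multiple-testing correction is applied across the DeLong
  matrix.

## Problem sizes

Default simulated cohorts are 351 patients (the reference size); calibration
checks use 10,000–20,000 draws so binomial noise is well under the
tolerances being checked; the headline direction experiment uses 3,510
patients (10× the reference cohort) so the qualitative claims (LRT
p < 0.001, AUC gain in the forest validation) are far from the noise floor;
GA-versus-exhaustive comparisons use 8 candidate features so full
enumeration (256 subsets) is exact.

## Known limitations

* Per-site prevalences after global calibration deviate slightly from their
  table targets (the shift that pins overall prevalence moves every site);
  the per-site table is treated as a shape prior, not a contract.
* The severity table's midbrain/pons rows overlap by design (a tegmental
  lesion is also counted under its laterality row), mirroring conventional
  tabulation rather than a partition.
* The chained imputation is single-imputation with prediction draws; it
  does not propagate imputation uncertainty (no multiple imputation
  variance pooling).
* Real-data performance magnitudes (e.g. a specific AUC for a specific
  grading system) are properties of patient cohorts and cannot be
  established from this package's simulations.
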