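# Methods

## Setting

`riskseg` implements repeated cross-sectional latent-class segmentation of
high-risk primary-care patients. For each observation wave (a calendar
year), the cohort is the set of patients who (a) were actively assigned to a
primary-care panel for some portion of the year and (b) carried a top-decile
predicted 1-year hospitalization risk in at least one week of the year. The
entry date is the first top-decile week. Each patient is represented by 26
binary chronic-condition indicators, set to 1 when at least one coded
encounter for the condition falls in the 2-year lookback window from entry.
Waves are modeled independently; patients may enter or leave the high-risk
population between waves.

## Latent class model

Indicators are modeled as a finite mixture of products of Bernoullis.
Patient *i* with indicator vector *y<sub>i</sub>* ∈ {0,1}<sup>J</sup> has density

  P(y_i) = Σ_k π_k Π_j ρ_kj^{y_ij} (1 − ρ_kj)^{1 − y_ij}

with class weights π on the simplex and item probabilities ρ ∈ (0,1)^{K×J}.
Indicators are conditionally independent given class. Estimation is by EM:

- E step: τ_ik ∝ π_k Π_j ρ_kj^{y_ij}(1 − ρ_kj)^{1−y_ij}, computed in log
  space with log-sum-exp normalization.
- M step: π_k = Σ_i τ_ik / n; ρ_kj = Σ_i τ_ik y_ij / Σ_i τ_ik, clamped to
  [1e-4, 1 − 1e-4] to avoid boundary lock-in and log(0).

Multistart: each start initializes responsibilities from per-row Dirichlet(1)
draws followed by an M step; 20 starts for K ≤ 5, 40 above, best
log-likelihood kept. Convergence: absolute log-likelihood change < 1e-6 or
500 iterations. A start that empties a class (total responsibility ~0) is
abandoned and recorded. All randomness derives from one integer seed through
`numpy.random.SeedSequence(seed, spawn_key=(K, start))`, so results are
reproducible and independent of execution order.

Fit statistics: with p = (K−1) + K·J free parameters,
AIC = −2LL + 2p, BIC = −2LL + p·ln n, and adjusted BIC = −2LL +
p·ln((n+2)/24) — the standard sample-size-adjusted variant; the exact
adjustment differs across software, so it is isolated in one function and
documented here. Relative entropy E = 1 − Σ_ik(−τ_ik ln τ_ik)/(n ln K)
summarizes class separation (1 = crisp, 0 = uninformative); it is undefined
(NaN) for K = 1.

## Model selection

The 2–7 class grid is fitted per wave. Class indices are arbitrary under
label switching, so every fit is canonicalized: classes sorted by descending
π, ties broken by the first ρ column. Selection rules:

- `min_bic` / `min_abic` — the criterion minimizer;
- `default` — walk K upward, stopping at the last K before the BIC
  improvement falls below 1% of |BIC| or entropy drops below 0.8;
- `manual:K` — an explicit override. Interpretability of the class profiles
  cannot be automated; applied segmentation work routinely overrides pure
  fit criteria, so the manual rule is first-class and is recorded in the
  selection report.

## Assignment with abstention

A patient joins the modal class only when max_k τ_ik ≥ 0.5 (inclusive; a
0.5/0.5 tie resolves to the lower class index). Otherwise the patient is
UNASSIGNED. Because no class weight exceeds 0.5, abstention identifies
patients whose indicator vectors are genuinely ambiguous between classes
rather than merely noisy. Raising the threshold can only shrink the
assigned set (tested monotonicity).

Groups are profiled by per-condition prevalence and mean ± SD condition
count, then labeled deterministically by prevalence lift over the cohort
average: a condition is elevated in a group when its lift is ≥ 0.15
(absolute prevalence); a group elevated on ≥ 60% of conditions is "High
Complexity"; one with no elevated conditions is "Low Diagnosis"; otherwise
the configured condition family (cardiometabolic, mental health, substance
use) holding the most elevated conditions gives its label, with ties flagged
as compound labels for manual renaming. The thresholds are configuration,
chosen so that the default synthetic truth reproduces the five canonical
labels; real analyses are expected to override labels by inspection.

## Two-wave stability

Waves are fitted independently, so classes are matched by minimizing total
L1 distance between ρ profiles over all bijections (Hungarian assignment on
the K×K cost matrix; verified against brute-force permutation enumeration).
Population-level stability is the signed percentage-point prevalence drift,
overall and within matched groups. Individual-level stability classifies
every wave-1 patient's wave-2 status with precedence

  DIED (death date ≤ end of wave-2 year) → NO_CARE (no risk score recorded
  in the wave-2 year) → HIGH_RISK_RETAINED (≥ 1 top-decile week) →
  IMPROVED (scores present, none top-decile),

which makes the four categories exclusive and exhaustive; death dominates
because later records are artifacts once a death is recorded. The
transition table is reported as row percentages of wave-1 group (including
UNASSIGNED) over wave-2 outcomes; cell counts sum to the wave-1 cohort. The
switch rate is the share of dual-high-risk patients whose aligned group
changed, with UNASSIGNED counted as a category in both waves.

## Synthetic cohort generator

Real registries of this kind are not redistributable, so the package ships a
generator whose outputs have the same shape as the registry extracts
(encounters, weekly risk scores, panel intervals, vital status) plus the
latent truth, making parameter recovery the primary validation surface.

Default truth (all values configurable):

- K = 5 classes over J = 26 conditions with mixing (0.25, 0.20, 0.17, 0.27,
  0.11): cardiometabolic-elevated, mental-health-elevated, substance-use-
  elevated (with secondary mental-health burden), low-prevalence, and an
  elevated-everywhere class whose expected condition count (~11.5) dominates
  the cohort mean (~6); profiles are contrasted enough that the 5-class
  structure is recoverable at n = 5,000 and relative entropy sits near 0.83.
- Boundary patients (8% of draws by default) model the low-confidence
  sub-population: a patient is drawn from the 50/50 blend of two random
  classes' item probabilities, *conditioned by rejection sampling on the
  realized vector being posterior-ambiguous* (max τ < 0.5 under the
  generating parameters). The conditioning matters: unconditioned blend
  draws are decisive over 26 indicators ~90% of the time, which would leave
  the unassigned category nearly empty. With it, thresholded assignment
  abstains on roughly 8% of the default cohort and assigned shares fall
  near 23/18/16/25/10% of patients.
- Risk scores are percentile-style values with an explicit top-decile flag
  (score ≥ 0.9); the upstream risk model itself is out of scope, only
  decile status matters. Entry weeks are uniform over the wave year, each
  patient gets a handful of weekly records, and weeks before entry stay
  sub-decile so the entry week is the first flagged week. Encounter dates
  are uniform over the 730-day lookback (the analysis tests only window
  membership). Panel intervals cover the wave year with random margins.
- Wave-2 dynamics: per-class probabilities of death / risk improvement /
  leaving care, remainder retained high-risk; defaults are calibrated so
  class-weighted aggregates land near 14.2 / 25.3 / 1.3 / 59.2% with the
  high-complexity class least likely to improve and most likely to die.
  Retained patients redraw their class from a row-stochastic kernel
  (diagonals 0.60–0.76) and redraw indicators with per-condition
  persistence 0.85 — chronic diagnoses usually recur in coding, but the
  lookback definition lets indicators drop. Deaths are dated between the
  waves; leavers lose panel coverage and weekly scores; improved patients
  keep sub-decile scores.

What the generator does **not** emulate: new wave-2 entrants (the real
second-wave cohort refreshes, which is why observed populations stay
compositionally stable; here the wave-2 cohort is the retained subset, so
between-wave prevalence comparisons inside the pipeline reflect selection
and persistence, not population drift — the sampling-noise drift bound is
therefore checked on two independent same-truth cohorts), coding intensity
and utilization patterns, within-class indicator correlation (real
comorbidities violate conditional independence, which is one reason real
cohorts have more low-confidence patients than a crisp mixture), and any
ICD-level ontology (codes are opaque tokens mapped 1:1 to conditions).
Passing tests demonstrate the estimator and reporting stack are correct
under the model's own assumptions, not that a real registry would yield
these groups.

## Numerical and design choices

- Lookback window is the closed interval [entry − 730 days, entry]; 730
  days avoids leap-year ambiguity and includes diagnoses coded on the entry
  day. Panel overlap with a year is any nonzero day-level overlap. Week
  identity is the provided `week_start` date; no ISO-week recomputation.
- Duplicate encounters are idempotent; unmapped codes are dropped with a
  logged count; cohort patients without qualifying encounters keep all-zero
  rows (sparse rows are legitimate model input — the low-diagnosis group).
- EM log-likelihood is monotone up to 1e-8 slack (asserted in tests);
  posterior rows renormalize to 1 within 1e-10.
- Two independent modal classifications at per-wave accuracy *a* agree at
  rate ≈ a²; with the default truth this puts same-group agreement for an
  unchanged patient near 80%, so observed switch rates combine true class
  change with classification noise. The generator exposes both knobs
  (transition kernel vs. profile separation) but claims no decomposition.

## Problem sizes

Validation runs use cohorts of 3,000–50,000 synthetic patients: parameter
recovery at n = 20,000 (max |π̂−π| < 0.02, max |ρ̂−ρ| < 0.03 after
matching), model-order recovery at n = 5,000 per replicate (min-BIC picks
K = 5 in ≥ 8/10 replicates), calibration checks at n = 50,000 with 3-SE
binomial tolerances, and the end-to-end two-wave pipeline at n = 20,000 per
wave. These sizes keep the full suite to a few minutes while leaving
binomial standard errors well inside the asserted tolerances.

## Known limitations

- No covariates on class membership, no sampling weights, no missing-data
  handling (synthetic inputs are complete by construction), and no latent
  transition analysis — the repeated cross-sectional design is the point.
- The adjusted-BIC variant and multistart/convergence defaults are
  documented choices, not bit-for-bit reproductions of any commercial LCA
  implementation.
- Group labels from the lift rule are a reproducible default; clinical
  review may rename them, especially for compound (tied) labels.
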