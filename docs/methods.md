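# Methods

This note records the models, the defaults and why they were chosen,
the numerical conventions, and what the synthetic generator does and
does not emulate.

## Cohort model and conventions

A cohort is a samples × analytes matrix joined to clinical records.
Analytes are either `gene_tpm` (transcripts per million, ≥ 0) or
`cell_percent` (deconvolved infiltration percentages in [0, 100]).
Survival cells follow the grammar `NUMBER [ "(" NUMBER ")" ] [ "+" ]`:
months, an optional bevacizumab-adjusted alternative in parentheses,
and `+` for censoring. Design choices:

- Primary months drive every analysis by default; the parenthetical
  alternative is kept and can be selected with `use_alt_months`.
- Group medians (`group_median`) treat censored months as plain
  numbers — that is how clinical summary tables print medians — while
  the survival module handles censoring properly.
- Months are stored as floats; fractional values (e.g. day-converted
  follow-up, × 12/365.25) are accepted.
- Analyte names are case-sensitive and matched exactly (PD-L1 ≠ PDL1).
- "Total immune" is the sum of the eight modeled cell subsets. Whether
  the upstream assay models it independently is not documented; the sum
  is the only definition computable from the subset percentages.
- A zero survival time is retained with a warning (one discovery-cohort
  patient has PFS 0).

## Threshold biomarker

Candidates are midpoints between consecutive distinct sorted values,
both directions. "Jointly optimizing LOO specificity and sensitivity"
is read as maximizing sensitivity + specificity (Youden-style); ties
break by higher accuracy, then the smaller cutoff, then
high-is-positive — purely for determinism, since any point in a tie set
is equally supported. The reported table prints the full-data cutoff
but all performance metrics come from leave-one-out predictions. A fold
whose training half holds one class predicts that class; an all-tied
training vector yields a degenerate rule predicting the training
majority. Boundary values (exactly at the cutoff) call the positive
class in either direction.

Percentages are rounded half-away-from-zero for presentation only;
undefined entries (0/0) are flagged and rendered `-`, never fabricated.

One calibration fact worth stating: under null labels the LOO accuracy
of this classifier centers near the 50% chance rate, slightly below it
from per-fold overfitting — not at the majority rate. A balanced
sens + spec criterion has no reason to prefer the majority class, and
the test suite asserts the measured behavior.

The per-analyte p-value is the two-sided rank-sum test (exact
enumeration for n₁ + n₂ ≤ 25 without ties; otherwise the tie-corrected
normal approximation without continuity correction, which tracks a
permutation p within 0.02 in the suite's checks). An all-tied sample
returns p = 1.

## Multidimensional biomarker

Two-step selection on the long + short samples only:

1. **Subset search.** Top-k (default 5) analytes by LOO accuracy then
   p-value; all 2^k − 1 subsets train forests with default
   hyperparameters; LOO misclassification count decides. Ties prefer
   more analytes, then the subset whose members rank higher.
2. **Grid search.** On the chosen subset, every grid point is LOO
   -scored; the earliest minimum wins; the final model is refit on all
   samples while the reported scores remain the winning point's LOO
   fold scores (no sample ever influences its own fold's forest — an
   instrumented invariant in the tests).

Defaults: 100 trees (the conventional library default for an
unconfigured forest), ⌊√p⌋ features per split, minimum leaf 1,
unlimited depth, bootstrap on. The grid spans trees {100, 300} ×
features-per-split {1..|subset|} × min leaf {1, 2} × depth
{unlimited, 3}. These axes cover the hyperparameters that matter at
n = 19 (deeper grids were measured to change no selection on the
synthetic cohorts while multiplying runtime several-fold; a full
default-grid pipeline run takes ~4 min on one CPU). Reproducibility:
one master seed; each LOO fold's forest is seeded master + fold index.

Scores: s = P(short) − P(long) from tree vote fractions; class = long
iff s < 0 (a 50/50 vote calls short). The sign convention puts the
long group at negative scores, matching the reported group medians
(−0.7 long, 0.6 short) of the assay's plotted biomarker value, whose
exact scale is otherwise undocumented. ROC treats short (higher s) as
positive; AUC is the trapezoidal integral and equals the Mann–Whitney
U/(n₁n₂) on the same scores.

The selection is deliberately not nested: the subset is chosen once,
then the grid winner's LOO predictions are reported, following the
stated order of the original two-step procedure. A fully nested
re-selection inside each fold would give more conservative error
estimates; that is a known limitation, not an oversight.

## Association statistics

- **Trend test** (Cuzick 1985, Wilcoxon-type): midranks R_i, integer
  group scores l_j (1, 2, 3 in short < intermediate < long order),
  T = Σ l_i R_i, E[T] = (N+1)/2 Σ n_j l_j,
  Var[T] = (N+1)/12 (N Σ n_j l_j² − (Σ n_j l_j)²) times the tie factor
  1 − Σ(t³−t)/(N³−N); two-sided normal p (one- vs two-sidedness is not
  documented for the original analysis; two-sided is the conservative
  choice). All values tied → z = 0, p = 1. With two groups and no ties
  the statistic reduces exactly to the rank-sum normal deviate.
- **Spearman**: midrank rho with the t-approximation
  t = r√((n−2)/(1−r²)) at every n (the cohorts of interest, n = 26 and
  n = 378, are beyond exact tables); |r| = 1 reports the limiting p = 0;
  zero variance flags the pair undefined.
- **Median split**: stable sort, lower half vs upper half, so sizes
  differ by at most one and ties at the median are assigned in sorted
  order.
- **t-tests**: pooled-variance unpaired or difference-score paired,
  two-tailed; zero-variance contracts: equal means → p = 1, unequal →
  limiting p = 0.
- **Fold change**: ratio of arithmetic means (mean expression), p from
  the t-test; medians are available to callers by computing on
  transformed inputs.

## Survival

Kaplan–Meier via the product-limit estimator (lifelines). The log-rank
test is Mantel–Haenszel: per event time a 2×2 table contributes
expected events and hypergeometric variance; chi² = (O−E)²/V, 1 df. The
hazard ratio is the O/E estimator with CI
exp(ln HR ± 1.96√(1/E₁ + 1/E₂)) — no Cox model is fit, because the
reported analyses pair HRs directly with log-rank tests. Quartile
stratification takes round-half-up(n/4) per tail (378 → 95), stable
order breaking ties.

## Synthetic cohort generator

The generator defines the study conditions for every simulation-based
test: outcome groups of sizes 11 / 7 / 8; log-normal TPM (the published
analyte table spans five orders of magnitude, from tens to ~10⁵ TPM,
so a log-scale family is the only sensible choice) with additive
per-group effects on the log scale; correlated gene blocks through a
Gaussian copula whose latent correlation is 2 sin(π ρ/6) so the
*Spearman* correlation of the output matches the requested ρ (the
ICOS–CTLA-4 block defaults to ρ = 0.89); cell subsets drawn on the
logit scale and rescaled so their sum lands near a configured
total-immune mean of 17.5% (SD 3); and per-group exponential survival
with hazards ln 2 / median for medians 76 / 24 / 6 months, censoring
probabilities 0.7 / 0.2 / 0.05, and a 100-month horizon. Overall
survival adds an exponential progression-to-death extension (mean 12
months).

The `study_shaped_fixture` configuration sets the 40 analyte locations
from the published discovery-cohort group medians (short-group shift =
log median ratio, intermediate at half), latent SD 0.6. What the
generator does **not** emulate: assay measurement error and
deconvolution uncertainty, compositional coupling between genes and
cell fractions, non-exponential survival shapes, and covariate
structure (age, CA125, debulking are carried but not generative).
Passing tests therefore demonstrate correctness of the estimators and
selection machinery under a faithful idealization, not performance on
real assay data — on the fixture the planted effects are clean enough
that the multidimensional biomarker typically reaches perfect LOO
accuracy, which real cohorts will not.

## Problem sizes in the test suite

Monte-Carlo suites use seeded, fixed replicate counts chosen for a
single-CPU desk run: 200 seeds for threshold-oracle equivalence and
planted-effect power, 150 for null calibration of the generator, 100
for hazard-ratio recovery, 2000 for type-I error of the rank-sum and
t-test pipelines, 10⁴–10⁵ draws for permutation oracles, and 12 seeded
replicates (50-tree selection forests) for recovery of a planted
analyte by the power-set search.
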