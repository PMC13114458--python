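# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices, and the known limitations of `radgex`. Nothing
here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Single-sample gene-set scoring

Scores are a rank-based running-sum statistic computed per sample on
log2(FPKM + 1) expression. With genes ordered by decreasing expression
(ties broken by gene id, so scores are platform-independent), the score
of set S is Σ_i [P_in^w(i) − P_out(i)], where P_in^w is the cumulative
in-set fraction weighted by rank^τ and P_out the unweighted out-of-set
fraction. Defaults:

- `weight_exponent` τ = 0.25 — the common convention in the single-sample
  enrichment literature; τ = 0 gives the unweighted statistic whose in-
  and out-of-set running fractions each end at exactly 1.
- `kernel_transform` on — a per-gene Gaussian-kernel CDF estimate across
  samples (bandwidth sd/4) applied before ranking. The literature on this
  family of scores conflates the pure rank statistic with the kernel-CDF
  variant; both are implemented behind the flag so the choice is explicit
  and testable. Without the kernel the score is invariant to any strictly
  monotone per-sample transform (asserted as a property test).
- `normalize` on — all scores divided by the global (max − min). The
  downstream analyses z-score per pathway, so this only affects reported
  raw scores.

Zone modules: per zone, a two-sided Wilcoxon rank-sum test (scipy's
Mann–Whitney implementation, asymptotic) of each gene in-zone vs all
other zones, BH-FDR across genes, retention at FDR < 0.05 and |difference
of mean log2(FPKM+1)| > 1, ranked by FDR (ties: larger |Δ|, then gene id)
and truncated at top-k = 200. The fold-change filter is a difference of
means on the log scale because a ratio of means is ill-defined with
zero-inflated FPKM.

## Zone → subcompartment mapping

Primary map: CT, CTmvp → ET; CTpan → NET; IT, LE → ED. Replicate samples
within one zone are averaged first so patients with more replicates do
not dominate; zones mapped to the same subcompartment are then combined
by mean (median under variant S3). The composition-baseline diagnostic
correlates (Spearman) a patient's aggregated score with the number of
zones that composed it; the indicator is configurable (e.g. a binary
CTmvp-availability flag) because the concern it probes is the CT-only vs
mean(CT, CTmvp) heterogeneity of the ET score.

## Feature reduction

1. Near-zero-variance: drop constant columns, and columns whose
   most-common/second-most-common frequency ratio exceeds 19 (= 95/5)
   while distinct values are < 10% of rows — the defaults of the widely
   used caret implementation, which names the rule but not the settings.
2. Correlation pruning at |Spearman ρ| > 0.90, with a deterministic drop
   rule: repeatedly take the worst offending pair and drop the member
   with the larger mean absolute correlation to all retained features
   (ties: lexicographically larger id). Reference implementations are
   order-dependent; this rule is stable and guarantees all surviving
   pairs satisfy the bound.
3. Supervised univariate screen, only for the frameworks that use it:
   per-subcompartment Spearman + BH within subcompartment (associational
   branch, full data) or a single patient-level pass (inside each CV
   fold). Eligibility is min FDR < 0.10; ranking by raw p with feature-id
   tie-break; cap 5.

Spearman p-values use the tie-corrected t approximation, except n ≤ 9
with untied data, where the exact permutation null of ρ is enumerated
(cached per n) — leave-one-patient-out training sets in small cohorts
make tiny-n reproducibility matter.

## Mixed-effects association

Both models of each pair are random-intercept Gaussian LMMs estimated by
maximum likelihood with an exact profiled likelihood: at fixed variance
ratio ψ = σ²_b/σ²_e the GLS solution and σ̂²_e are closed-form (rank-one
corrections by per-patient row sums), leaving a one-dimensional bounded
scalar optimization in log ψ (xatol 1e-12, explicit ψ = 0 boundary
check). This gives machine-precision estimates in microseconds, which the
permutation and calibration loops require; agreement with an independent
mixed-model implementation is asserted in the tests to < 1e-6 in
log-likelihood.

- Omnibus test: LRT χ² = 2(ℓ_full − ℓ_null) floored at 0, referred to
  χ²(k) by default. The asymptotic χ² reference is known to be
  anticonservative at ~50 observations with k = 5 (the exact
  fixed-effects analogue has type-I error ≈ 0.10 at nominal 0.05); a
  small-sample F-type reference (`lrt_reference="f_adjusted"`,
  F = (e^{T/N} − 1)(N − p_full)/k on F(k, N − p_full), exact in the
  fixed-effects case) is provided and much better calibrated. The χ²
  reference stays the default because it is the field's convention for
  this analysis and keeps reported p-values comparable to the motivating
  study; the calibration consequence is documented, not hidden.
- R² decomposition (Nakagawa–Schielzeth): var(Xβ̂) is the population
  variance of the fitted fixed-effect predictor over the analysis rows.
  ΔR²m = R²m(full) − R²m(null) can be slightly negative through variance
  repartitioning; that is expected, not an error.
- Coefficients: Wald z intervals (labelled as such), Holm-corrected
  across the k radiomic terms.
- Standardization: response z-scored globally; features z-scored within
  subcompartment (globally under variant S7). Zero-variance features are
  dropped with a warning.
- Diagnostics (reported, never pass/fail): Shapiro–Wilk on conditional
  residuals (BLUP-shrunken patient means removed) and exact
  leave-one-patient-out refits as the influence measure — exact refits
  are affordable at these sizes and avoid the approximations of
  Cook's distance in mixed models.
- Covariate ladder A–D (none / +age / +MGMT / +subtype): covariates enter
  both the full and the null model, so the LRT always isolates the
  radiomic block. Model D at cohort scale has a high
  parameter-to-observation ratio; results carry that caveat.

## Nested prediction

Patient-level tables average scores and features over each patient's
available subcompartments (median under S3). The response is analyzed on
its standardized scale (MAE is therefore in SD units — the alternative
raw-scale convention would change only that column). Per LOPO fold:
screen on the 27 training patients, fit the elastic net on the ≤ 5
selected features, predict the held-out patient; folds selecting nothing
predict the training mean, which keeps the pooled metric defined and
penalizes empty models (an all-empty run has R²cv = 1 − (n/(n−1))² < 0
exactly). R²cv pools residuals against the overall mean ȳ_all.

Elastic net: coordinate descent on the objective
(1/2n)‖y − β₀ − Xβ‖² + λ(α‖β‖₁ + (1−α)/2‖β‖²), λ path log-spaced over
three decades from the smallest all-zero λ, features standardized with
training statistics, coefficients returned on the original scale.
Hyperparameters: α by the minimum mean inner-CV MSE over its path, then
λ by the one-standard-error rule at that α (the SE taken at the MSE
minimizer). Inner folds are deterministic: patients rank-sorted by
response and dealt round-robin under a seeded label permutation —
reproducibility at n = 27 beats randomness here. The descent kernel is
numba-compiled because the fully nested permutation test re-runs it on
the order of 10⁵ times; it is verified against the soft-threshold closed
form on orthonormal designs (≤ 1e-8) and against an independent
implementation on general designs.

Uncertainty: percentile bootstrap on (y, ŷ) pairs (B = 1000, seeded,
degenerate resamples redrawn) — this conditions on the fitted
predictions and captures metric sampling variability only. The primary
inferential tool is the fully nested permutation test.

## Permutation frameworks

- Patient-level (mixed-model branch): a random permutation of patient
  labels moves each patient's scores as a block onto another patient's
  feature rows, matched by subcompartment; unmatched rows are dropped for
  that permutation (redrawn if > 50% of rows would vanish), or a
  strict same-availability-pattern shuffle can be requested. Features
  stay fixed at the pre-selected set, so this null does **not** account
  for adaptive selection — by design, mirroring the exploratory branch.
- Fully nested (predictive branch): scores shuffled across patients and
  the entire nested CV re-executed, screening included.
- p = n_extreme/N with ties counted as extreme; p = 0 is reachable. A
  (+1)/(N+1) smoothed option exists but is off by default because the
  plain convention is what makes reported values like 0.050/0.055
  attainable.

A structural property worth knowing: on a null cohort the in-fold screen
usually selects nothing, and every all-empty arrangement yields the
identical mean-predictor R²cv, so the nested permutation null carries an
atom at that value and the p-value is conservative (piled toward 1)
rather than uniform. The machinery itself is calibrated — with a
continuous statistic (screen cut above 1, λ at the CV minimum) the same
code produces uniform p-values (asserted by KS test). The one-SE rule
contributes additional atoms through its all-zero solutions.

## Multiplicity

BH step-up implemented directly (sort, scale by m/rank, cumulative min
from the top, cap at 1) so it is bitwise-identical to its brute-force
definition; padding to a fixed family size appends p = 1 placeholders
for untested hypotheses. The padded variant inflates the denominator
deliberately and is not a formal FDR guarantee, since the placeholders
are not p-values under any null. Holm is the standard step-down. Both
are cross-checked against an independent implementation in the tests.

Policy: the associational campaign pads to the full pathway family at
threshold 0.05; the predictive campaign pads the nested permutation
p-values to the same family at threshold 0.10 and additionally reports
the BH correction restricted to the pathways actually tested.

## Sample-size criteria

For a continuous-outcome model with p predictors, anticipated R², target
shrinkage S: (i) n = p/((S−1)ln(1−R²/S)); (ii) n = 1 + p(1−R²)/δ with
δ = 0.05; (iii) residual-SD precision within a 10% multiplicative margin
requires ≥ 234 residual df, n = 234 + p + 1; (iv) mean-outcome precision
(1.96·σ_resid/√n within 10% of the anticipated mean) — undefined for a
standardized zero-mean outcome and then reported as not applicable, which
is the package default. N_min is the max over applicable criteria. The
inversion (`min_detectable_r2`) bisects the R²-dependent criteria (i)–(ii)
to 1e-6; the precision criteria do not depend on R² and are excluded. A
closed-form alternative from the expected-shrinkage heuristic
S ≈ 1 − (p/n)(1−R²)/R², i.e. R² = 1/(1 + (1−S)n/p), is exposed because
published "minimum detectable R²" figures are often computed that way;
at n = 28, p = 5, S = 0.9 the two conventions give 0.749 and 0.641
respectively, and the difference is a statement about which criterion is
being inverted, not a numerical discrepancy.

## Synthetic cohorts

The generator emulates the statistical structure the analyses assume,
not tumor biology:

- Design: fixed zone counts reproducing the unbalanced cohort
  (CT for all 28 patients, CTmvp for 9, CTpan for 15, IT/LE for 7, with
  exactly 6 patients carrying all three subcompartments → 50 rows).
  Counts and probabilities are configuration, since per-zone availability
  beyond these anchors is not published.
- Expression: log2-scale Gaussian per-gene means; per-set per-patient
  latent t_p driving a coherent shift of the set's genes; per-set zone
  affinities (subcompartment differences); per-zone marker-gene blocks
  (+2 log2) so module derivation has a truth; back-transform
  2^x − 1 truncated at 0, so the downstream log2(FPKM+1) transform
  recovers the generative scale. Background (uncoupled) sets additionally
  receive per-sample coherent activity noise (sd 0.5), which puts the
  intraclass correlation of their scores near 0.5 — the moderate-ICC
  regime the mixed models are designed for — instead of the ~0.97 a
  purely patient-level signal would give. Planted sets keep the exact
  latent → expression chain so a coupling's signal fraction has its
  literal meaning.
- Radiomics: iid standard-normal features, plus near-zero-variance
  columns (one repeated value in ≥ 96% of rows), equicorrelated blocks
  (factor construction, within-block ρ configurable), and planted
  couplings x = β·t_p + b_p + ε with β available from a target signal
  fraction β²/(β² + σ² + σ_b²).
- Covariates: age ~ N(58.5, 7.8) truncated to [30, 85], MGMT ~
  Bernoulli(13/28), four-level subtype — matching the reported cohort
  moments.
- Seeding: one integer seed feeds a `SeedSequence` spawn per block
  (availability / expression / radiomics / covariates), so sub-tables are
  reproducible in isolation.

What passing tests on these cohorts do **not** show: real radiomic
feature distributions (heavy tails, scanner effects), spatial structure,
the zone-to-subcompartment mapping error of real anatomy, or FPKM
library-composition artifacts. Survivor counts of the reduction stages on
real data (3920 → 3860 → 597 in the motivating study) depend on the real
feature table and are logged, never asserted.

## Problem sizes used in the checks

The stochastic suites run at deliberately chosen desk scales: calibration
of the LRT at the 28-patient/50-observation design over 1000 null
simulations; nested-permutation calibration on 8-patient cohorts at 99
permutations × 200 replicates; leakage contrast on 20 null cohorts with
200 candidate features; planted-coupling recovery on 10 cohorts of 200
patients. These sizes make the suites exact enough to be meaningful while
keeping a full run in minutes.

## Known limitations

- The χ²(k) LRT reference is anticonservative at cohort scale (see
  above); the F-type reference is the calibrated alternative.
- Satterthwaite/Kenward–Roger denominator degrees of freedom and
  random-slope models are not implemented; the omnibus inference is the
  ML LRT.
- The nested permutation p-value is conservative on no-signal pathways
  (atom structure above).
- Coefficient intervals are Wald, not profile.
- S4b/S4c sensitivity subsets are declared but undefined upstream; S9 is
  an alias of covariate model D; S6/S8 raise with an explanation.
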