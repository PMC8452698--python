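# Methods

## The analysis model

The pipeline treats each trait as a pair of independent GWAS of the same
underlying per-SNV effects: an earlier discovery study and a later, usually
larger, replication study.  All inference is done on summary statistics
(per SNV: alleles, effect, SE, P, allele frequency, INFO, N); no
genotype-level data are touched.  Matching is by rsID only — no
chromosome/position fallback, no liftover — and allele harmonization
handles effect/other-allele exchanges only.  Strand flips and palindromic
SNVs are deliberately out of scope: files that disagree on strand should be
fixed upstream.

Effects are carried internally on the log scale and converted to odds
ratios before any classification.  Binary-trait effects are assumed to be
log-odds and are exponentiated.  Quantitative-trait effects are assumed to
be standardized (SMD-like) betas and go through the Chinn conversion
ln OR = d·π/√3, which rests on the logistic approximation to the normal
(the logistic distribution's standard deviation is π/√3).  For input files
whose betas are on a raw outcome scale, `harmonize_pair(...,
standardize_beta=True)` rescales by beta/(se·√n) first; the default assumes
the inputs are already standardized.

### Replication rule and rates

An SNV is *eligible* when its discovery P is below the genome-wide
threshold 5×10⁻⁸, and *replicates* when its replication P is also below
threshold and the aligned ORs agree in direction (strict inequalities on
both sides of 1; an OR of exactly 1 — a measure-zero event — counts as
incongruent).  Direction is evaluated on the aligned, pre-normalization
scale, so the call is invariant to jointly reciprocating both ORs.

Rates are binomial proportions with Wilson score intervals throughout.
Wilson was chosen over the Wald/normal interval because it behaves
correctly near 0 and 1, where several per-trait rates sit (e.g. 547/549),
and because pooled counts + Wilson reproduce the published pooled intervals
that this pipeline's example table carries.  Two pooling routes exist:
summed counts (default; the fixed-effects answer when every SNV is weighted
equally, defined for any number of traits) and classical inverse-variance
fixed-effects pooling of per-trait proportions on the proportion or logit
scale.  The two agree exactly under rate homogeneity but diverge when
member rates are heterogeneous, because inverse-variance weights
n/(p(1−p)) concentrate on near-degenerate traits; with the bundled
nine-trait table they differ by ~12 percentage points.  That divergence is
a property of the estimators, not a bug, and is why pooled counts is the
default reporting route.  Degenerate members (k = 0 or k = n) get the
Haldane–Anscombe 0.5 continuity correction on the inverse-variance route
and are flagged.

### Stratification boundaries

Discovery P bins (5e−8 to 5e−9, 5e−9 to 5e−10, 5e−10 to 5e−11, < 5e−11)
are upper-inclusive in P: a boundary value belongs to the bin whose label
starts with it (P = 5e−9 exactly → "5e−9 to 5e−10"), matching the
convention of tables written "5e−8 to > 5e−9".  Normalized-OR bins
(1–1.05, …, 1.3–1.4, > 1.4) are lower-inclusive (OR = 1.05 exactly →
"1.05–1.1").  Both schemes partition the eligible set, which is asserted as
a test invariant.

### OR normalization

Published analyses of this kind report all ORs "above 1".  The inversion is
anchored on the discovery OR: when or_d < 1 both cohorts' ORs are
reciprocated, preserving their relative direction; an OR of exactly 1 is
left untouched.  Anchoring on one cohort (rather than inverting each OR
independently) keeps the discovery→replication comparison meaningful for
direction-incongruent SNVs; independent inversion would fold incongruence
away.  The choice of anchor cohort is a genuine free choice; the discovery
cohort was picked because selection and binning are defined on it.

### Winner's curse and the effect-change regression

The effect-change model is OLS of replication OR on discovery OR on the
normalized scale, pooling SNVs across traits, fit separately for the
replicated-only and all-significant subsets and per trait scope.  The slope
is reported with its 95% CI and as percent change, (slope − 1)·100.  An
intercept is included by default; since the percent-change reading is exact
only through the origin, a no-intercept variant and a log-OR diagnostic
scale are provided.  Two caveats the tests make explicit:

* Selection at a significance threshold inflates discovery effects
  (winner's curse), pushing the slope below 1 even when both cohorts are
  unbiased.  The analytic reference is the truncated-normal conditional
  mean E[β̂ | β, |β̂/se| > z] implemented in `expected_shrinkage`, verified
  against numerical integration and Monte Carlo.
* Even without selection, sampling noise in the predictor attenuates the
  OLS slope by the reliability ratio τ²/(τ² + se²) (errors-in-variables).
  The "no systematic change without selection" property therefore only
  holds where se ≪ τ, and is tested in that regime.

The sign of the effect change on real data is data-specific (quantitative
traits have been observed to show increases); the package asserts the
mechanics and the selection-induced shrinkage direction only.

### Prediction model

A maximum-likelihood logistic regression predicts replication per eligible
SNV from: normalized discovery OR (numeric), P-value category (reference
level "5e−8 to 5e−9"), −log₁₀ P as the continuous P term (raw P underflows
across ~40 orders of magnitude), trait type, discovery MAF, replication
INFO, and the replication/discovery sample-size ratio.  Rows missing MAF or
INFO are dropped and counted; the model is refused below 50 complete rows.
Data are split in half at random (reproducibly from a seed); metrics come
from the held-out half: AUC with a DeLong 95% CI (midrank computation),
and sensitivity/specificity with Wilson CIs at either the Youden-optimal
test-ROC threshold (default — published sensitivity ≈ specificity patterns
indicate an ROC-optimal operating point) or a fixed 0.5.  McFadden's
R² = 1 − llf/ll₀ uses the closed-form intercept-only log-likelihood as
ll₀, so the intercept-only model scores exactly 0.  Single-level
categorical terms (e.g. one trait type in the data) are dropped from the
formula automatically.  Perfect or quasi-perfect separation — including
rank-deficient designs — is flagged and replaced by an L2-penalized refit
whose coefficients carry no standard errors.

## The synthetic generator

`simulate_pair` emulates the statistical structure the analysis assumes:

* **True effects**: point-normal — zero with probability `frac_null`
  (default 0.9, a realistic hit fraction for a dense SNV panel), otherwise
  Normal(0, τ²) on the standardized (quantitative) or log-odds (binary)
  scale.  Defaults τ = 0.05 (quantitative) reflect the small per-allele
  effects typical of polygenic traits; binary scenarios use τ = 0.08
  log-odds (OR ≈ 1.08 per SD of effect distribution).
* **Allele frequencies**: MAF ~ Uniform(0.05, 0.5) — common variants, the
  regime where rsID matching and the SE approximations are reliable.
* **Sampling noise**: independent per cohort, Normal(0, se²) with the
  large-sample standard errors se = 1/√(2n·f(1−f)) (quantitative) and
  se = √(1/(2n·φ(1−φ)·f(1−f))) (binary, case fraction φ; the standard
  logistic score approximation — only the scaling with n, f, φ is relied
  on, not exactness).  P values are two-sided Wald.
* **File-level noise**: with probability `p_allele_swap` the replication
  record's alleles are exchanged and its effect negated (so harmonization
  has real work to undo — a test proves the calls are bit-identical to an
  unswapped run); a fraction `p_missing_rsid` of SNVs is absent from the
  replication file; INFO ~ Beta(20, 2) (median ≈ 0.92, mimicking
  well-imputed panels) appears only in the replication table.
* **Seeding**: one master seed; each randomization stage draws from its own
  spawned child stream, so toggling one stage never perturbs another —
  this is what makes the swap-involution and missing-rsID tests exact.

What the generator does **not** model: linkage disequilibrium between SNVs
(every SNV is independent, so "number of SNVs" behaves like "number of
loci"), population structure, sample overlap between cohorts, strand
errors, and binary-trait ascertainment beyond the case-fraction term in the
SE.  Passing tests therefore demonstrate the pipeline's correctness and the
qualitative phenomena (winner's curse, threshold sensitivity, predictability
of replication), not the numeric rates of any particular real data set.

### The default synthetic study

`synth.study_scenario` fixes four traits — two binary (discovery 20–25k,
replication 20–40k) and two quantitative (discovery 20–30k, replication
45–60k) — with distinct replication/discovery sample-size ratios per trait,
~60–80k SNVs each, 10% non-null.  This yields ~5,000–5,500 eligible SNVs
per run with moderate binary and high quantitative replication: the regime
where discovery OR, P category and trait type all carry signal about
replication.  Four traits (not two) are required so the sample-size ratio
is not collinear with trait type in the prediction design.  At these sizes
a full end-to-end run takes ~1–2 s, and the whole test suite stays under
half a minute.

## Numerical choices

* Duplicate rsIDs within a file: keep the smallest P (deterministic);
  remainder counted under `duplicate_id`.
* Out-of-range optional fields (EAF, INFO, N) are demoted to missing rather
  than dropping the row; only stages that need them (prediction) exclude
  such SNVs.
* Underflowed P values are clipped to the smallest positive double.
* Tables are written with 15 significant digits (round trip preserved to
  ≥ 12), reports with 10 (bit-stable on rewrite).
* McFadden values within 1e−12 of 0 are clamped to exactly 0 (Newton
  convergence residue on intercept-only fits).

## Known limitations

* Counting is per SNV, not per locus: without LD-based clumping, a single
  association peak contributes many correlated SNVs, and real-data CIs will
  be anti-conservative relative to the nominal binomial model.
* The binary-trait SE formula ignores covariate adjustment and
  case-control imbalance beyond φ(1−φ).
* The inverse-variance pooling route is sensitive to near-degenerate member
  rates (see above); use pooled counts unless per-trait weighting is
  specifically wanted.
* The effect-change slope conflates winner's curse with errors-in-variables
  attenuation; it quantifies the observed discovery→replication change, not
  the bias decomposition.
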