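# Methods

## Scientific setting

Chronic cigarette-smoke (CS) exposure and natural aging perturb the lung
transcriptome in strikingly similar ways. This package implements the
full analysis chain for studying that interaction in multi-study mouse
inhalation experiments: (i) identify age-regulated and
exposure-regulated genes from log2 expression matrices; (ii) quantify
their overlap; (iii) train a sparse linear "transcriptomic clock" that
predicts chronological age from the expression of control (sham,
fresh-air) animals; and (iv) read exposure-induced *age acceleration*
off the clock as delta age = predicted − chronological age, in months.

Because the real microarray datasets require repository downloads, the
package ships a first-class synthetic-data generator whose default
configuration emulates their structure, with known ground truth for
every quantity the downstream stages estimate.

## Synthetic data generator

Expression of gene *g* in sample *s* follows

    x_gs = b_g + m_g · f(a*_gs) + step_g · a_s + u_{study(s),g} + ε_gs

* `b_g` — baseline log2 level, uniform on [4, 12] (typical microarray
  intensity range).
* `m_g` — aging slope in log2 units/month, carried by `n_age_genes`
  genes; magnitude uniform on `slope_range` (default 0.1–0.4), 60 %
  positive. `f` is linear by default (a saturating alternative with an
  8-month scale is available).
* `step_g` — an age-independent exposure step (default magnitude
  0.6–1.5 log2 units) carried by *exposure-only* genes.
* `u` — per-study, per-gene batch offset, N(0, batch_sd²), default
  batch_sd = 0.3; this is what makes leave-one-study-out validation
  harder than random holdout.
* `ε` — i.i.d. N(0, σ²) measurement noise, default σ = 0.25.

Exposure acts through an *acceleration factor* `a_s`: 1 under continuous
CS, 0 for sham and HTP-aerosol arms, and an exponential decay with a
1-month half-life after the switch time for cessation/switch arms (the
reversal is qualitative in the source data; no rate is identifiable, so
the half-life is a free simulation parameter, not an inference target).

The planted acceleration moves *effective age* `a*_gs = age_s + Δ·a_s`
for the **overlap genes** — the fraction of exposure-responsive genes
drawn from the age set (`overlap_fraction`, default 0.62). The shift
rides along each such gene's own aging slope rather than acting as an
independent effect. This is a deliberate design choice: it is exactly
the signal a clock trained on controls can translate back into months,
making "recovered group mean delta ≈ planted Δ" a well-defined recovery
target. Exposure-only genes respond with the step effect instead; age
genes outside the overlap do not respond to exposure at all.

One consequence is worth stating explicitly: the clock selects predictor
genes from the age-trending genes without knowing which of them shift
under exposure, so the recovered delta age is attenuated by the planted
coverage of the age set. The default scenario plants 220 exposure genes
with 62 % overlap, covering 136/150 ≈ 91 % of the age genes; the
expected recovered delta for Δ = 2 months is therefore ≈ 1.8 months.
This mirrors the situation in real data, where most but not all clock
genes are exposure-responsive. The planted-overlap *recovery* check
instead uses an equal-sized configuration (150 age, 150 exposure genes,
strong slopes) in which the recovered age∩exposure fraction equals
`overlap_fraction` by construction.

### Default study design

Three studies, every animal 2 months old at exposure start
(age = 2 + exposure months throughout; ages are real-valued months and
never coerced to integers):

| study  | time points (months) | arms (n per group)                          |
|--------|----------------------|---------------------------------------------|
| study1 | 1, 2, 3, 4, 6, 8     | sham (8), CS (8)                             |
| study2 | 1, 2, 3, 4, 6        | sham (8), CS (8), HTP (8)                    |
| study3 | 1, 3, 6              | sham (8, 8, 7), CS (8), HTP (8); cessation and switch (8) at 3 and 6, leaving CS at 2 |

This yields 111 sham samples, C(6,2)+C(5,2)+C(3,2) = 28 within-study
sham time-point pairs for the age contrasts, and 6+5+3 = 14 CS-vs-sham
pairs. Gene universe: 2 000 genes (a deliberate desk-scale reduction of
a genome-wide array; all rates and thresholds are per-gene, so the
reduction affects only multiplicity burden).

### What the generator does not emulate

Probe-level noise, intensity-dependent variance, correlated gene
modules, sex/strain covariates, and array-specific missingness. Tests
passing on this generator demonstrate the estimators recover the
planted generative structure; they do not certify performance on real
arrays, where variance moderation and batch structure matter more.

## Differential expression

Per-gene two-group contrasts on the log2 scale with a fixed orientation
(oldest − youngest; treated − control — never auto-detected). The
pooled-variance t-statistic is optionally moderated: per-gene variances
s²_g (d_g df) shrink toward a prior s₀² with weight d₀,

    s̃²_g = (d₀ s₀² + d_g s²_g) / (d₀ + d_g),   df = d_g + d₀,

with (d₀, s₀²) estimated by the method of moments on log variances
(exact digamma/trigamma moments of log scaled-χ²; trigamma inverted by
Newton iteration). When the spread of log variances does not exceed
chi-square sampling noise the estimator returns d₀ = ∞ (complete
shrinkage, normal reference distribution); d₀ = 0 recovers the ordinary
pooled t. Moderation is computed per contrast; moderating across all
arrays jointly would pool information further but ties contrasts
together, and is noted here as the untaken alternative.

Genes with zero sample variance in both groups are reported flat
(t = 0, p = 1) with a logged flag so set operations stay total — even
though shrinkage could lend them a finite statistic.

BH-FDR is the literal step-up definition, q_(i) = min_{j≥i} p_(j)·n/j
capped at 1, adjusted within each contrast. A gene is *regulated* when
|log2 FC| > log2(1.5) and FDR < 0.05 in at least one contrast; the
fold-change criterion is two-sided (both directions are biologically
meaningful and both occur). A configurable exclusion list removes genes
that are invalid by design (e.g. a gene knocked out in some of the
underlying strains); it is empty by default in the synthetic scenario.

## Overlap analysis

* Venn partition of the two regulated sets; the overlap percentage is
  reported relative to the age set.
* Signed maximum fold change: per gene, the log2 FC of largest
  magnitude across contrasts, sign retained; ties resolve to the
  lexicographically earliest contrast id.
* PC1 loadings: SVD of the column-centered (per-contrast) fold-change
  profile; loadings are the unit-norm gene weights of component 1,
  inertia = 100·λ₁/Σλ. Columns are centered, not scaled, by default
  (a scale switch exists); the sign is fixed so the loadings correlate
  non-negatively with the gene-wise mean fold change. The age and
  exposure loadings are compared by Pearson correlation over the shared
  gene universe.

## The transcriptomic clock

LASSO objective (1/2n)‖y − Xβ‖² + λ‖β‖₁ on per-gene standardized
expression (population sd; zero-variance genes are unselectable) and
centered ages, minimized by cyclic coordinate descent with
soft-thresholding. Implementation notes:

* The kernel alternates full sweeps with sweeps over the current active
  set and uses warm starts along a descending grid of 100 log-spaced λ
  from λ_max = max_g |x̃_g'ỹ|/n down to 10⁻³ λ_max.
* Convergence criterion: max_j ν_j·Δβ_j² ≤ tol (the objective-change
  form; default 10⁻¹⁰ for model fits, tighter in solver tests). A
  per-coordinate-step criterion can stall on the flat plateaus of
  nearly unpenalized fits when p ≫ n; the objective form terminates
  there correctly.
* All inner products are compiled scalar loops (numba-jitted when
  available, identical pure-numpy fallback otherwise) with a fixed
  summation order, so fits are bitwise reproducible across runs and
  BLAS thread counts.
* λ is chosen at the minimum mean validation MSE over 5 seeded folds
  (each fold standardized on its own training samples); ties break
  toward the larger λ, i.e. the sparser model. The one-standard-error
  rule is deliberately not used.
* The final model is an OLS refit of age on the *raw* log2 expression
  of the selected genes, so coefficients read in months per log2 unit;
  a rank-deficient refit is ridge-stabilized (ε = 10⁻⁸) with a logged
  warning, and an empty support falls back to an intercept-only model.
* Prediction on a matrix missing some model genes imputes each missing
  gene at its training mean, up to a 20 % missing fraction (both the
  policy and threshold are configurable); beyond that it errors,
  listing the genes. This supports cross-platform application where
  some predictor genes are absent.
* The clock predicts absolute age in months (baseline 2 months at
  exposure start plus exposure time), not time-on-study.

## Evaluation and delta-age inference

* Random holdout: repeated 75/25 splits stratified by study (so no run
  trains on a single study by chance), refit per run, MAE on both
  partitions; the pooled validation MAE is the mean of per-run
  validation MAEs. Degenerate runs (< 2 distinct training ages) are
  skipped and recorded, never silently dropped.
* Leave-one-study-out: one round per study. With nonzero batch sd the
  held-out study's offsets cannot be learned, so LOSO MAE exceeds
  holdout MAE — the expected ordering, verified in tests.
* Delta age is summarized per exposure group (pooled over time points,
  with a per-time-point breakdown available). Each group is compared to
  sham by Welch's unequal-variance t-test (the conservative default
  when group variances differ), plus a classical one-way ANOVA across
  groups. Star codes: **** p<10⁻⁴, *** p<10⁻³, ** p<0.01, * p<0.05,
  "." p<0.1, ns otherwise. No multiplicity correction is applied across
  the per-group comparisons; each is reported as-is.
* Power/type-I calibration replicates fix the clock (fitted once on the
  sham data) and regenerate fresh exposed/sham groups (n = 20 each)
  from the same planted truth — new noise, same gene effects and batch
  offsets — then re-run prediction and the Welch test. The type-I
  scenario compares two exchangeable fresh-air groups (the generator's
  Δ = 0 null), so the rejection rate measures the calibration of the
  delta-age test machinery itself. An exposure that perturbs
  transcription without accelerating aging is *not* a calibrated null
  for this test: if an exposure-responsive gene happens to enter the
  clock support it biases the group deltas by a constant, a real
  false-positive mode of transcriptomic clocks worth keeping in mind
  when interpreting small delta-age effects.

## Problem sizes and tolerances

The shipped analyses run at desk scale by design: 2 000 genes, ~320
samples, 100 holdout runs in the acceptance script (25 in the test
suite), 200 power and 1 000 type-I replicates. Numerical comparisons in
tests: solver KKT residuals ≤ 10⁻⁶ (typically ≤ 10⁻⁹ at the tested
sizes), BH vs. brute force ≤ 10⁻¹², hand-computed t/p to 10⁻¹⁰.

## Known limitations

* The moderated-t prior is estimated per contrast from as few as ~2 000
  genes; with very small gene universes the d₀ estimate is noisy.
* The generator's linear age trend makes the clock's job easier than
  real transcriptional aging, which saturates and drifts; the
  saturating trend option narrows but does not close that gap.
* Delta-age recovery is attenuated by the planted overlap coverage (see
  above); with real data the analogous attenuation is unknowable.
* The CLI runs single-threaded and keeps the full matrix in memory;
  genome-scale matrices (≫ 10⁵ genes) would need chunked I/O.
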