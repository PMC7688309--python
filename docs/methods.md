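# Methods

This note records the statistical models, the synthetic-data design, and
the numerical choices behind `screg`, in enough detail to judge what the
passing tests do and do not establish.

## Accessibility model

A cell's library holds *C_j* distinct molecules; *k_j* reads drawn with
replacement (unbiased PCR) sequence any given fragment with probability
*s_j* = 1 − (1 − 1/*C_j*)^{k_j}, computed via `expm1`/`log1p` so it is
accurate for *C_j* in the millions (`access.sequencing_probability`;
*C_j* = 1 is special-cased to the indicator *k_j* ≥ 1). Assuming a
fragment enters the library proportionally to its peak's accessibility
*A_i* and to *C_j*, E[O_ij] ∝ *C_j s_j A_i*, giving the estimator
*A_i* = *Z*·Σ_j O_ij / Σ_j C_j s_j. The denominator is shared across
peaks, so after the Σ_i A_i = 10⁶ normalization (*Z* is defined as the
constant enforcing it) the estimator coincides, on a single cell subset,
with the relative form 10⁶·Σ_j O_ij/Σ_ij O_ij; the complexity term
matters when un-normalized scores from different subsets (donors, age
groups) are compared — `normalize=False` exposes that scale.

Cell-fraction statistics (m, s, RS) use the strict rule "accessible iff
O_ij ≥ 1" on integer counts. A peak with m = 0 in every partition has
undefined RS and is reported as NaN, never 0: a zero would fabricate
evidence of absence in one partition. The statistics are invariant to
duplicating all cells of a partition (depth invariance), which the tests
assert.

## Synthetic cohort

The generator (`simulate`) emulates a 3-age-group × 3-donor design with
three cell types (AT2 50%, AT1 30%, macrophage 20%), 250 cells and 250
nuclei per donor by default, and 300 peaks of width 400 bp spaced 2–8 kb
apart on a 2-Mb genome — about one peak per 5 kb, similar to a dense cCRE
map. Counts are 0/1/2 per peak per cell: each allele opens with
probability logistic(baseline + age shift + module factor) and an open
allele is observed with probability *s_j* — exactly the sampling model the
estimator inverts, so the accessibility estimator is unbiased by
construction.

* **Depth model.** *C_j* ~ LogNormal(9.2, 0.5) with a per-donor
  multiplicative shift (sd 0.4 on the log scale, so donors differ
  systematically); *k_j* ~ Poisson(r_j·C_j) with a per-cell depth factor
  r_j ~ LogNormal(log 1.0, 0.6). The per-cell factor matters: with
  constant reads-per-molecule, *s_j* ≈ 1 − e^(−r) is nearly the same for
  every cell and the complexity correction would be untestable.
* **Co-accessibility modules.** Five modules of four consecutive peaks
  share a per-cell latent factor with the standard parametrization:
  loading σ√ρ plus idiosyncratic σ√(1−ρ) with σ = 2 and ρ = 0.6, so the
  pairwise latent correlation is exactly ρ. At these settings the binary
  (cell-level) correlation between members is ≈ 0.17–0.20 against a ±0.02
  background. The first member of each module hosts a gene TSS, so planted
  links are promoter links.
* **Age-dynamic peaks.** Sixty peaks carry monotone logit shifts of
  ±0.9 per age step, alternating up/down — two planted temporal
  archetypes.
* **Expression.** Each (gene, cell type) has a base expressing fraction
  drawn U(0.05, 0.6); the first five genes add +0.15 per age step. A
  nucleus expresses with that probability and contributes 1 + Poisson(0.6)
  UMIs.
* **Genome side.** Motif consensus sequences (an AP-1-like 8-mer and an
  NF-κB-like 10-mer) are written into peaks; disrupting variants change
  one consensus base, neutral ones sit in peaks away from motifs, plus
  singletons and 4-bp indels to exercise the filters. The 11-mer weight
  table covers every k-mer of every variant's 19-bp windows with N(0, 1)
  weights plus a +4 bonus for k-mers containing a planted consensus.

All randomness flows from one seed through named substreams
(CRC32-derived spawn keys), so cohort and genome generation agree on the
layout and each can be re-run alone, bit-identically.

What the generator does **not** model: doublets, batch effects, fragment-
level positioning, Tn5 sequence bias, cluster-assignment errors (cluster
labels are taken as given downstream), linkage disequilibrium between
variants, and trans (inter-chromosomal) structure. Passing recovery tests
therefore show the statistics behave as designed under the stated sampling
model, not that they are robust to these real-data complications.

## Co-accessibility estimator

The engine is a graphical lasso with an entry-wise penalty matrix
(ρ_ab = λ₀√(d_ab/window)), solved by ADMM (eigendecomposition Θ-step,
entry-wise soft-threshold Z-step, μ = 1, ≤ 300 iterations, tolerance 1e−6
on scaled primal/dual residuals). The soft-thresholded iterate is
returned, so zeros are exact. An independent proximal-gradient solver in
the test suite confirms the solution on small windows to 1e−3 in partial
correlations.

Estimation choices that matter, and why:

* **Depth from out-of-window peaks.** Normalizing a window's counts by
  totals over that same window imposes an exact sum constraint
  (compositional closure) that manifests as spurious negative partial
  correlations; totals are therefore computed over peaks *outside* the
  window.
* **Unpenalized auxiliary nodes.** Log depth and the metacell's
  age-group / cell-type / donor composition enter the model as extra,
  unpenalized variables, so group-level covariation (two peaks both more
  open in adults) is conditioned away rather than reported as
  co-accessibility.
* **Cross-fit embeddings.** Metacell neighbourhoods are built from the
  TF-IDF/SVD embedding of the *other* genome half. Building neighbourhoods
  on the very counts being scored groups cells by their shared noise and
  manufactures correlation between independent peaks; with a few hundred
  peaks this artifact dominates. Cross-fitting removes it at the cost of
  two metacell builds per run.
* **Scale-invariant metacell size.** Each run aggregates
  n/300 cells per metacell (clamped to [5, 50]); at the reference
  15,000-cell subset size this reproduces 50-member metacells, and at desk
  scale it keeps enough aggregates (~300) for the precision-matrix
  estimate. `build_metacells` itself defaults to k = 50.
* **Calibration.** λ₀ is the smallest value (20 bisection steps) at which
  ≤ 5% of pairs farther apart than half a window have nonzero partial
  correlation, measured on ≤ 20 sampled windows of an all-cells metacell
  build.

Per-cluster and subset runs pool into one score array per link (the most
literal reading of the ensemble merge); `include_cluster_runs=False`
gives subset-only arrays, since mixing 1-Mb and 250-kb window scales in
one t-test is a recognized ambiguity. Pairs never evaluated by a run are
missing from its array, not zero. The sensitivity/false-discovery
guarantee is evaluated at 4,500 cells (within the "2,000+ cells" regime
the property targets): at ~2,250 cells the irreducible cell-level noise
floor (binary correlation sd ≈ 1/√n ≈ 0.021) puts an appreciable
one-sided tail above the fixed 0.05 score threshold no matter how the
ensemble estimates it, which is a sample-size statement, not an estimator
defect.

## Negative-binomial age dynamics

Per-peak NB2 GLMs (log link, log-total offset) are fitted by IRLS with a
step-halving line search; the likelihood-ratio test compares
group + covariates against covariates alone (χ², 1 df). Technical
covariate columns are added only while they increase the design rank and
leave residual degrees of freedom — a dataset identifier that is
one-per-donor drops out automatically.

Dispersion is the weak point of n = 3 + 3 designs, and three choices fix
its calibration: (1) per-peak estimates maximise the **Cox–Reid adjusted**
profile likelihood (−½ log det X'WX), since the plain profile MLE is
biased sharply downward when the mean model consumes most of six
observations; (2) the shrinkage target is the **common dispersion** — the
maximiser of the *summed* CR-APL over a 200-peak subsample — rather than a
mean of noisy per-peak estimates, which inherits their bias; (3) per-peak
values are shrunk 50/50 on the log scale toward the common value and then
**floored at it**, because at this sample size an underestimated
dispersion is the dominant source of false positives while an
overestimated one merely costs power. With these choices the null
fraction of raw p < 0.05 sits in 0.03–0.06 across simulation seeds while
4-fold planted effects (μ = 50, dispersion 0.1) are recovered with ≥ 80%
power at FDR < 0.05.

Offsets are log totals over all peaks, so a strongly asymmetric planted
signal (many peaks shifted the same way) would bias the offset — the
balanced up/down design of the generator avoids this; for real data with
asymmetric composition a robust size factor would be the next step.

The Davies–Bouldin implementation follows the R_xy/DB formulas literally,
including degenerate cases (coincident centroids → DB = +∞; all-singleton
clusters → DB = 0); it agrees with scikit-learn's implementation on
generic data, which the tests cross-check. K-means runs on unit-sum-scaled
rows with 20 seeded restarts per K; ties in DB break toward the smaller K.

Locus-restricted tests are pooled-variance two-sample t-tests on per-donor
within-donor scores s_ij (the cross-partition RS is exposed as an
alternative measurement column), reported at raw p — this mode is
deliberately uncorrected, mirroring the targeted re-examination of a
candidate locus.

## Expression statistics

QC keeps genes detected in ≥ 3 nuclei and nuclei with 500–4,000 detected
genes (both bounds inclusive), iterating gene-then-cell passes to a fixed
point so the operation is idempotent. Log-normalization is
ln(1 + 10⁴·x/total) — natural log. Expressing fractions use the ≥ 1 UMI
rule and are reported at full precision; display rounding (one decimal of
a percent) is a report-layer concern. Age tests are pooled-variance
two-tailed t-tests on per-donor fractions (Welch available via
`equal_var=False`).

## Variant scoring

PWM scanning computes log-odds in bits against the 0-order background at
every placement on both strands. Match p-values are exact: per-position
scores are rounded to integers at scale ×1000 and the full score
distribution under the background is built by dynamic programming;
zero-probability bases contribute −∞ paths that simply leave the finite
mass (their tail probability is correct by omission). The test suite
checks the DP against brute-force enumeration of all 4^w words up to
w = 8. The default match threshold is p < 1e−4, the scanning
convention's canonical default; PWM width is not restricted (point-mass
toy motifs of width 3 are legal).

Delta scores are defined for SNVs only (a fixed ±9-bp window is not
well-defined for indels; indels still go through motif scanning with
allele-length-aware windows). Absent k-mers fall back to their reverse
complement when the table's strand policy allows, else raise naming the
k-mer. The permutation null reassigns the weight multiset across all
k-mers jointly — one permutation, one re-scored cohort — with n_perm
= 100 by default; z is (observed − null mean)/null sd, p two-sided
normal, q Benjamini–Hochberg across variants, and sd = 0 yields missing
values rather than infinities. Commonness folds each population frequency
to min(f, 1 − f) and requires > 0.01 strictly in at least one population
(the threshold is configurable; > 0.05 is a documented alternative
convention).

Variant–peak overlap uses: 1-based position p overlaps 0-based half-open
[start, end) iff start ≤ p − 1 < end. `io.variant_to_interval` is the one
sanctioned bridge between the two coordinate conventions; coordinates are
otherwise treated as a single abstract genome build, with liftover out of
scope.

## Problem sizes and determinism

The default test suite runs the full planted-link recovery at 4,500 cells
(~2–3 minutes), NB calibration and power at 2,000 peaks (~10 s each),
locus-t-test calibration at 5,000 replicates, permutation-null calibration
at 1,000 variants × 100 permutations, and Davies–Bouldin K recovery at
5,000 × 3 profiles — sizes chosen so the whole suite completes in a few
minutes on one CPU while keeping binomial/multinomial standard errors
well inside the asserted bands. Every stochastic step takes an explicit
seed; `hypothesis` property tests draw only seeds, so failures reproduce.
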