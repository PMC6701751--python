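# Methods

This note documents the models, estimators, numerical choices, and
known limitations of the package. Everything quantitative stated here
is computed by the test suite or the worked example; nothing is quoted
from external results.

## Questionnaire scoring and trait extraction

**Scoring.** Subscales are item sums after reverse-coding. The scoring
unit for missingness is the subscale: if more than 20% of a subscale's
items are missing for a subject the subscale is left missing; otherwise
each missing item is imputed with the mean of the subject's observed
items in that subscale. The 20% rule uses a strict inequality (exactly
20% missing is still scored).

**Covariance network.** Pearson correlations between subscales
(pairwise-complete, minimum 3 complete pairs; undefined correlations
stay missing rather than being zeroed). The network keeps the
`floor(density * n_pairs)` strongest coefficients at the default
density 0.10. "Strongest" ranks *signed* r by default: in trait
batteries most informative correlations are positive, and anticorrelated
scales are expected to land in different communities rather than be
linked; an `absolute` mode is available. Exact ties straddling the
cutoff are resolved by lexicographic pair order and logged.
Communities are found by greedy modularity maximization (deterministic;
Louvain available behind a seed). Community labels are canonicalized by
(size, smallest member), so partitions are order-invariant.

**PCA traits.** Columns are z-scored (sample SD); the correlation
matrix is eigendecomposed; components with eigenvalue > 2.0 are
retained (the retention threshold is applied *before* rotation, the
standard convention) and varimax-rotated with Kaiser normalization
(tolerance 1e-6, max 1000 iterations; the implementation matches R's
`stats::varimax` to machine precision when run at equal tolerance,
which the suite verifies through `Rscript`). Scores use the regression
method on standardized data; because the rotation is orthogonal and
the unrotated PCA scores are white, rotated scores remain exactly
orthogonal on the fitting sample (checked to 1e-8). Sign
indeterminacy is fixed by flipping each component so its
largest-|loading| subscale loads positively. `variance_explained` is
the retained unrotated eigenvalue sum over the number of variables.
Replication across cohorts refits the PCA per cohort and pairs
components by Hungarian assignment on |loading correlation|
(projection of one cohort's loadings onto another is available as an
option). Loadings with |loading| >= 0.4 are flagged for display.

## Connectome-based decoding

**Edges.** Connectivity is the Fisher z (arctanh) of pairwise Pearson
correlations between parcel-averaged time courses; matrices are
symmetric with zero diagonal, vectorized over the strict upper triangle
of the node order (272 nodes -> 36,856 edges). |r| = 1 is clipped at
arctanh(1 - 1e-7) and flagged; constant channels yield missing edges,
never zeros. The first 120 volumes of a run are dropped before
correlation (field stabilization), leaving 990 of 1,110.

**Edge screen.** Each edge is regressed on the trait with iteratively
reweighted least squares using Tukey bisquare weights (tuning constant
4.685), scale re-estimated each iteration as MAD/0.6745 of the
residuals (centered at zero), standard errors from the H1-type
covariance with Huber's small-sample correction, p-values from the t
distribution with n-2 df. These are the conventions of the common
`robustfit`-style implementations; the suite enforces agreement with
statsmodels `RLM` to 1e-6. Edges with two-sided p < 0.05 are split by
slope sign into positive and negative sets (slope sign, not the sign
of the underlying connection). An OLS screen is available
(`method="ols"`) and is used by some calibration tests for speed; it
changes the estimator, not the protocol.

The screen is the package's hot loop (3 folds x ~40 leave-one-out
refits x 36,856 edges x 200 permutation replicates), so it is a numba
kernel: per-edge scalar IRLS with a quickselect median and
scale-aware convergence (|change| < tol * (|coef| + scale), default
tol 1e-6, maxiter 50). On one CPU a full-edge fit takes ~0.2 s and the
complete 62-subject/272-node protocol with 199 full-re-run
permutations runs in about four minutes.

**Stability filter.** Within a training fold, an edge is kept only if
every leave-one-subject-out refit is significant at the same alpha
with the same sign (the LOO threshold equals the outer alpha). The
output is necessarily a subset of the full-training-set selection, so
only those candidates are refit, with early termination at the first
failing leave-out.

**Cross-validation.** Subjects are shuffled by seed and cut into k = 3
contiguous blocks (sizes differ by <= 1); each fold trains on 2/3 and
scores the left-out 1/3 by the summed z(r) over the selected edges,
per sign. Left-out sums are normalized with the *training* fold's
edge-sum mean/SD by default (leakage-free); within-test-fold z-scoring
is available by flag. Pooled left-out scores are correlated with the
observed trait, giving one r² per sign. A fold whose selection is
empty for a sign contributes no predictions for that sign and is
logged (a trait may be decodable from one sign only).

**Permutation test.** p = (1 + #{perm r² >= observed r²}) / (n_perm + 1)
with the trait vector permuted across subjects and the *entire*
selection + stability + scoring pipeline re-run per permutation
(default; the statistically correct null). A cheap `score` mode that
permutes only the observed/predicted pairing is provided for quick
checks and is labeled approximate — it does not propagate selection
noise. n_perm >= 100 is enforced; under the null generator the
full-mode p-values are uniform (KS-tested in the suite over 200
replicate pipelines at n_perm = 199).

**Consensus model.** Edges selected in 3/2/1 of the three folds get
weights 1.0/0.66/0.33, stored exactly as those decimals (not thirds);
weight-1.0 edges are the "most stable links". An edge selected with
opposite signs in different folds is dropped and logged. The
consensus-weighted edge sum applied to any session's matrix gives the
neurotrait score. Community summaries count model edges within/between
node communities ignoring weights; overlap between two models is
reported as |A∩B|, |A∩B|/|A| and Jaccard.

**Motion controls.** Edge mode removes, before selection, edges whose
values correlate with mean framewise displacement at p < 0.05; subject
mode partials mean FD out of the neurotrait-trait correlation.

## Reliability and associations

**ICC.** Two-way random-effects ANOVA (subjects x sessions). All four
standard forms are computed — absolute agreement vs consistency,
single vs average measures — because software labels conflate them;
absolute-agreement average-measures is the headline default. CIs use
the F-distribution constructions (Satterthwaite df for the
absolute-agreement forms); estimates and CIs match pingouin
numerically (the suite's independent oracle). Incomplete subjects are
listwise-deleted and logged. Degenerate tables (MSE = 0) collapse the
CI onto the estimate.

**Pain PCA** reuses the trait machinery with a fixed 3-component
retention. **Partial correlations** residualize both variables on
[1, covariates] and correlate residuals with df = n - 2 - q; the
3-variable case matches the closed form to 1e-10. **Consensus maps**
require every available replication cell (visit x cohort) to pass
uncorrected p < 0.05 with a common sign; adding a cell can never
create a consensus (monotonicity is property-tested). **Income
analyses** fit an ANCOVA-style linear model (sum-coded categorical
income and ethnicity, numeric education; type-III omnibus test), the
six pairwise bracket contrasts Bonferroni-corrected, and the binary
>$25,000 split; subjects with missing income are dropped with the
analysis n reported. Two-sided p-values throughout.

## ICA rules and time-series operators

Components are rejected if any ratio is strictly above its threshold:
edge-activation ratio > 0.45, white-matter+ventricle activation ratio
> 0.35, or high/low band-power ratio > 1 (0.05-0.1 Hz vs
0.008-0.05 Hz, one-sided periodogram integrated over half-open bands
(low, high] so the shared 0.05 Hz bin is counted once). Values exactly
at a threshold are kept. All firing rules are reported. Band-passing
uses a zero-phase (forward-backward) order-2 Butterworth filter;
nuisance regression removes a T x q regressor matrix (plus intercept)
by least squares, with regressors band-passed *before* regression, the
pipeline's stated order of operations.

## Synthetic cohort generator

The generator is the package's test bed; its defaults are the study
conditions the suite measures under.

* **Questionnaires.** subscale_j = Σ_k λ_jk f_k + ε_j with independent
  standard-normal factors, block loadings (36 subscales in 4 contiguous
  blocks, λ = 0.7) and Gaussian uniqueness (default SD √(1-λ²), giving
  unit variance). The population correlation matrix then has four
  eigenvalues of 1 + 8·0.49 = 4.92 against a bulk at 0.51, so the
  eigenvalue > 2 rule retains exactly four components explaining
  4·4.92/36 ≈ 55% of the variance — the regime the analysis assumes.
* **Connectivity.** Each planted edge carries background + β·f_k +
  subject intercept + session deviation; `edge_effect` is the
  population edge-trait correlation of a single session (default 0.5,
  the level at which the recovery guarantees are stated), with
  β = |r|·σ_noise/√(1-r²) and σ_noise = 0.10 on the Fisher-z scale
  (a typical between-subject spread). `session_icc` (default 0.85, the
  reliability regime of interest) sets σ²_b/(σ²_b+σ²_w) of the
  non-trait noise per edge; planted edges are slightly more reliable
  because the trait signal is subject-level. 50 edges are planted per
  trait and sign (disjoint across traits and signs). A separate
  random-intercept score generator supports exact ICC
  parameter-recovery tests.
* **Pain and SES.** Pain measures cross-load on factor 1 (intensity
  ~0.5, qualities ~0.4) and negatively on factor 4 (negative affect),
  with unit noise. Income is ordinal over four brackets via a latent
  y* = γ·f1 + ε (γ = -0.4 by default) cut at its population quartiles;
  education and ethnicity are generated from the income bracket (so
  they associate with income but not directly with the factors); sex
  and head motion (mean FD ~ N(0.11, 0.07), truncated) are
  independent.
* **Seeding.** One cohort seed expands into fixed-order per-stage
  child seeds (`SeedSequence(seed, spawn_key=(stage,))`), so every
  stage is independently and jointly reproducible, bit-for-bit.

What the generator does *not* emulate: raw 4-D fMRI, realistic motion
traces or physiological artifacts, non-Gaussian questionnaire
distributions (Likert discreteness, floor/ceiling effects), missing
data patterns, site/scanner effects, or correlated factor structures.
Passing recovery and calibration tests therefore demonstrates that the
estimators do what they claim under the assumed data-generating
process — not that real cohorts will yield effects of any particular
size. The worked example's r² ≈ 0.6 is a property of the planted
signal strength, not a claim about patients; likewise the
consensus-score ICC saturates near 1 because ~900 edges are averaged,
while per-edge reliability follows `session_icc`.

## Problem sizes used by the test suite

Deterministic rules are tested exactly. Statistical guarantees are
tested at the sizes the claims are stated for: planted-edge
sensitivity and the type-I rate on full 62-subject/272-node cohorts;
ICC recovery on 500 replicate 56 x 4 tables per grid point
(session_icc ∈ {0.3, 0.6, 0.9}, tolerance ±0.05); permutation
uniformity on 200 replicate 30-subject/30-node pipelines with
n_perm = 199 and the OLS screen (KS at α = 0.01); and one complete
robust-screen run at full scale with 199 full-re-run permutations,
asserted to finish within its 15-minute budget. The robust screen at
n ≈ 60 runs slightly liberal (selection fraction ~0.051-0.053 at
α = 0.05, asymptotic robust t), and the calibration band reflects
that.

## Known limitations

* The IRLS p-values are asymptotic; at small n the screen is mildly
  anticonservative (see above). The permutation test, which is what
  significance claims rest on, is exact by construction.
* Greedy modularity on sparse thresholded networks leaves weakly
  connected variables as singleton communities rather than forcing
  them into blocks.
* `income_analysis` uses plain pairwise t-tests with Bonferroni
  correction for the post-hoc contrasts (not pooled-variance
  model-based contrasts).
* The ICA rules operate on binary activation maps (a z-threshold
  option exists for continuous maps); the edge mask is assumed one
  voxel thick.
* Fold assignment is contiguous-block after a seeded shuffle; no
  stratification is attempted.
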