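# Methods

This note documents the models, estimators, and design choices behind
`affectdecode`, in the spirit of a statistical software methods appendix.
It states no empirical result that the test suite or the acceptance script
does not itself compute.

## 1. Behavioral model and reliability ceilings

A ratings table is long-format: one row per (respondent, image) with a
rating on a bounded scale (0–7 by default), an affect label (arousal,
valence, or beauty), an image category, and a dataset id. All reliability
operations act on one (affect, dataset) cell at a time and refuse mixed
tables.

**Group average.** The decoding target Y is the arithmetic per-image mean
over all respondents who rated that image. Images with fewer than two
raters are rejected, not imputed.

**Mean-minus-one (r_MM1).** For respondent i, the Pearson correlation
between their ratings and the group mean recomputed without them, over
exactly the images that respondent rated. This matters under sparse viewing
designs: restricting to the viewed subset keeps the statistic comparable
across respondents who saw different images. Zero-variance respondents
propagate as flagged NaN — never coerced to zero, never silently dropped.

**Split-half (r_split).** Respondents are partitioned into two equal
halves (odd pools drop one respondent at random per split); per-image means
are computed within each half over available raters; the two mean vectors
are correlated across images; the correlation is Spearman–Brown corrected,
2r/(1+r); the default is 10,000 splits with a percentile 95% CI. Images
unrated in one half are excluded from that split's correlation and counted.
The splitting scheme (global equal halves) is the package's reading of
"split the group data in half"; it is the variant under which the
variance-components prediction below is exact.

Under the generator's variance decomposition (shared s, idiosyncratic v_i,
trial noise v_e, m raters per image), the corrected split-half converges to

    r_split = s / (s + (v_i + v_e)/m),

which is also the squared correlation between the group mean and the latent
image effect. Note the convention this implies: r_split is already a
variance-ratio-like quantity, and the EVE score divides by its square
(Section 4), so a perfect decoder of the latent scores EVE = 1/r_split ≥ 1.
EVE values above 1 are therefore legitimate and are not clipped.

**Bootstrap of the pool.** Group-mean uncertainty is quantified by
resampling respondents with replacement (multinomial weights over the
pool), recomputing per-image means per replicate; an image losing all its
raters in a replicate carries the full-pool mean forward, flagged. CIs are
percentile bootstrap CIs throughout; bias-corrected variants are out of
scope.

## 2. Sparse random projection

Layers wider than 5,830 features are reduced to p = 5,830 columns with a
sparse random sign matrix R (D × p): entries ±√(√D/p) each with probability
1/(2√D), zero otherwise. This preserves squared norms in expectation
(E‖uR‖² = ‖u‖²) and, at p ≥ 4 ln(n)/(ε²/2 − ε³/3), pairwise squared
distances within (1 ± ε). For n = 900 and ε = 0.1 the bound evaluates to
5,830.6; the package floors it (5,830), with ceiling exposed for
conventions that round up. Narrower layers pass through unchanged — the
threshold equals p, so projection never *increases* dimensionality.

Dimensional consistency fixes R as D × p (P = FR with F being n × D). One
projection matrix is drawn per layer, seeded from (global seed, model id,
layer id) via CRC32-hashed SeedSequence spawning, so layers are independent
and every rerun is bit-identical. Whether to re-draw R per layer or reuse
one R per width is genuinely open; per-layer drawing was chosen because it
makes layer scores independent draws from the projection distribution
rather than sharing one realization's distortions.

## 3. Leave-one-out ridge

Targets and feature columns are standardized to mean 0, SD 1 (population
SD — the choice affects only scale and is recorded because conventions
differ) once on the full data before cross-validation. This mirrors
standard decoding practice and admits mild train/test leakage through the
standardization statistics; a `per-fold` mode that re-standardizes inside
every fold exists for sensitivity analysis and is off by default. Constant
columns are dropped with a logged count; a constant target is an error.

The LOO predictions use the exact linear-smoother identity
ŷ₋ᵢ = yᵢ − (yᵢ − ŷᵢ)/(1 − Hᵢᵢ) with the ridge hat matrix computed in the
primal (p ≤ n) or Gram/dual (p > n) form. The identity is algebraically
exact for ridge; the test suite verifies it against a naive per-fold refit
to 1e-8 relative tolerance on 200 random instances. λ = 10⁴ is the global
default and is not re-tuned per layer; `grid_search_lambda` (log grid
10⁻¹…10⁶, one Gram eigendecomposition for the whole grid, ties toward the
smaller penalty) is provided as a utility outside the default pipeline.
λ = 0 with p ≥ n raises with advice rather than returning a pseudoinverse
fit.

## 4. Scoring

Per layer: r(y,ŷ) across the pooled out-of-fold predictions, and
r²_EVE = r²/r²_split with the mean corrected split-half of the *matching*
(dataset, affect, group) cell. Grouped scoring recomputes both the accuracy
and the ceiling within each image group, the ceiling from the group's own
rating rows only; groups with fewer than 3 images are skipped with a log
line.

Best-layer selection takes the argmax of the cross-validated r itself with
exact ties broken toward the shallowest layer (logged). There is no
secondary selection/evaluation split, so best-layer scores carry the usual
optimistic-selection caveat; this is recorded here rather than hidden.

Depth is summarized two ways: ten equal-width bins of relative depth for
display, and per-model OLS slopes of r on *unbinned* relative depth for
inference (binning before regressing would launder the within-model
variance). The mean slope gets a bootstrap-over-models CI.

## 5. Robustness statistics

- **Bootstrap scores/rankings.** Best layers are selected once on the full
  pool; per replicate the group means are recomputed from a respondent
  resample and each model is rescored (fixed predictions) or its best-layer
  regression refit. Refitting every layer of every model per replicate is
  not done: layer selection is treated as a fixed design choice of the
  full-pool analysis. Two-sided bootstrap p-values use the sign-fraction
  convention 2·min(frac ≤ 0, frac ≥ 0), Holm-corrected over the declared
  family of model pairs; rank tabulations count, per rank position, how
  often each model attains it (columns sum to the number of replicates).
- **Paired tests.** Paired t per condition cell, Holm step-down across the
  family, and paired Hedge's g = mean(Δ)/SD(Δ) with the small-sample factor
  1 − 3/(4·df − 1). Identical samples give g = 0, p = 1; a nonzero
  constant shift leaves g and p flagged NaN rather than infinite.
- **Mann–Whitney.** Two-sided rank-sum via the standard tie-corrected
  implementation, exact for small tie-free samples.
- **Individual decoding.** A layer's features restricted to each
  respondent's viewed images, LOO-ridge-fit against their own ratings
  (respondents below a 20-image floor are skipped, logged); negative
  accuracies are reported as-is. The cross-respondent correlation between
  r_MM1 and mean individual accuracy quantifies the taste-typicality →
  decodability link.
- **Cross-decoding.** Off-diagonal cells fit once on the training subset
  (no LOO) and score r on a disjoint test subset; standardization uses
  training-row parameters applied unchanged to test rows — leaking test
  statistics would invalidate the transfer claim. Diagonal cells are the
  within-subset LOO accuracy. Partial train/test overlap is an error.

## 6. The synthetic generator

**What it emulates.** Rating x_ij = t_j + u_ij + e_ij with image-shared
latent t ~ N(0, s), stable rater-idiosyncratic preference u ~ N(0, v_i),
and trial noise e ~ N(0, v_e); an affine map centers the scale midpoint and
places ±4 SD at the scale bounds (clipping beyond is counted in the truth
record); optional integer rounding emulates the discrete 0–7 responses.
Each rater views a fixed-size uniform random subset of images
(round(coverage·n_images) — a fixed per-rater quota, as in designs where
every respondent views ~225 of 900 images), and the generator refuses
configurations that leave any image with fewer than two raters. Defaults
are n = 900 images, m = 40 raters per image, (s, v_i, v_e) = (1, 2, 2),
continuous ratings — giving an analytic ceiling r_split = 1/1.1 ≈ 0.909 and
a mean r_MM1 in the 0.4–0.5 range typical of real affect-rating pools.
Per-image rater counts of the original datasets are not published, so
m = 40 is a design choice, exposed in the config.

**Feature banks.** Let z be the standardized latent and define the
decodable signal g = √q·z + √(1−q)·η with η exactly orthogonalized noise
and q = f·r_split, where f is the designed decodable fraction. The deepest
layer then has designed accuracy r(y,ŷ)² = f·r²_split, i.e. designed
EVE = f: the decodable fraction is calibrated against the explainable
(noise-ceiling) variance, which is what makes f recoverable on the EVE
scale regardless of the rater configuration. Layer ℓ at relative depth d
carries g_ℓ = α(d)·g + √(1−α(d)²)·ξ (ξ again exactly orthogonalized), a
signal-*mixing* construction rather than a signal-*scaling* one: scaling a
signal block is undone by column standardization in the decoder and would
produce no depth gradient at all. The k signal dimensions receive g_ℓ times
a ±1 read-out weight vector; i.i.d. feature noise of SD `noise_scale`
overlays every dimension. α is any nondecreasing [0,1] → [0,1] profile
(`linear` default; `zero` gives the signal-free "untrained" analog with
identical shapes and depths). Defaults: 8 layers of width 64, k = 16,
noise SD 0.25 — deep enough SNR that the designed deepest-layer accuracy is
realized to within ~1%, with a clear monotone gradient across layers.

**Two-dataset simulation.** Each image category owns a dedicated block of
k feature columns; a category's read-out weights are drawn from a random
stream keyed by the category *name*, so a category present in both
datasets automatically shares its weights while others draw independently.
This design uses wide layers (512) with unit-or-larger feature noise
(SD 1.5): transfer between categories must be carried by the shared
read-out, not by a low-rank signal structure that would dominate the
prediction variance and produce large random-sign correlations even
between unrelated categories.

**Randomness.** All draws flow from one integer seed through named
SeedSequence streams (CRC32 of string tags), so every table, bank, split,
and bootstrap is exactly reproducible and independent components use
independent streams.

**What passing tests do and do not show.** The generator is Gaussian,
homoscedastic, and stationary: no rater drift, order effects, prompt
differences, heavy-tailed or bimodal rating distributions, or
category-dependent rater pools. Recovery results therefore validate the
*estimators* (that the pipeline measures what it claims under a known
truth), not distributional robustness on real behavioral data. Discrete
0–7 rounding is available but recovery statements are exact only in the
continuous case, which is why discretization is a flag rather than always
on.

## 7. Numerical choices and problem sizes

Zero-variance detection uses an absolute SD tolerance of 1e-12 on
standardized inputs; Gram eigenvalues are clipped at zero before
shrinkage; leverage ≥ 1 raises rather than dividing by zero. The
acceptance-scale tests run at the generator's reference conditions
(n = 900, m = 40) with 10,000 splits for the reliability recovery, 20
replicates per designed decodable fraction, 20 trained/untrained pairs, 10
depth and 10 transfer replicates, and split-half ceilings at 200 splits
inside replicated loops — sizes chosen so the whole suite completes in
well under a minute while keeping Monte-Carlo error far below the
recovery tolerances. Unit tests use smaller pools (40–300 images) where
the property under test does not depend on scale.

## 8. Known limitations

- Whole-data standardization before LOO is faithful to common decoding
  practice but mildly optimistic; use `per-fold` mode to bound the effect.
- Best-layer selection on the cross-validated r is itself optimistic; a
  nested selection split is deliberately out of scope.
- The bootstrap refit mode refits the best layer only, not the full layer
  sweep, per replicate.
- r_MM1 on exchangeable simulated raters concentrates around its
  variance-components value only as the per-respondent image count grows;
  with very sparse viewing it is noisy per respondent (as with real data).
- File-format support is deliberately minimal: long CSV for ratings,
  manifest + NPY for feature banks. No image handling, no network feature
  extraction — the pipeline begins at ratings tables and feature banks.
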