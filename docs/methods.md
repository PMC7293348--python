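# Methods

This note documents the models, the synthetic study the package simulates,
the numerical choices, and the places where the design was genuinely open.

## The measurement model

The unit of analysis is a voxel's *response magnitude* to one action
video: a per-condition GLM beta, taken as given input.  The study design
is condition-rich: 60 everyday actions, each depicted by one exemplar
video in each of two video sets, with responses estimated separately from
odd and even runs.  Thus every voxel carries four 60-vectors, indexed by
(set, split).

### Split-half and item-pattern reliability

Voxel split-half reliability is the Pearson correlation of the odd- and
even-run 60-vectors.  Two schemes are supported:

- **within_set** — correlate odd vs. even within each set, then average
  the two r-maps.  Sensitive to any reproducible response structure,
  including low-level image-driven structure; used for analyses that need
  early-visual coverage.
- **across_set** — correlate odd-run betas of one set with even-run betas
  of the other (both pairings, averaged).  This demands generalization
  across two different exemplars of each action, so purely image-driven
  voxels score low.

Item-pattern reliability flips the axis: for one condition, correlate its
multi-voxel pattern between splits over a chosen voxel subset.  The voxel
selection curve plots the mean item-pattern reliability among voxels
surviving each cutoff on a grid (−1 to 0.9, step 0.05; points with fewer
than 10 surviving voxels are marked unavailable).

**Plateau rule.**  The selected cutoff is the smallest grid value whose
mean item-pattern reliability lies within 5% (of the curve's total range)
of the curve's ceiling.  An earlier candidate rule — requiring two
consecutive near-zero marginal gains — turned out to fire on the flat left
segment of any realistic curve (no voxel has split-half r near −1, so the
curve is constant there), selecting the degenerate cutoff −1; the
within-band-of-ceiling rule instead lands just past the rise, which is the
behavior the selection procedure is meant to formalize.  If the band is
first reached only within the last two grid points, the curve has no
plateau; the function warns and falls back to maximizing
range-normalized reliability minus lost coverage,
`(y − y_min)/range − (1 − n/n_max)` — a deterministic trade-off that
reduces to "highest curve point that keeps most voxels".  Degenerate
inputs: a flat curve returns the smallest cutoff; NaN voxel reliabilities
(zero-variance voxels) are treated as −∞ and never survive.

### Ridge encoding with cross-set λ selection

For training set s, design columns (PCA component scores) are z-scored
with set-s statistics and each voxel's responses centered; the same
transform is applied to the held-out set's design.  The ridge solution
uses the eigendecomposition of XᵀX, which also yields the minimum-norm
(pseudoinverse) solution when λ = 0 meets a rank-deficient design.

The candidate grid is {0} ∪ 99 log-spaced values up to λ_max, the largest
λ whose solution is still *non-null*: max|w(λ)| > 10⁻⁶ · max|w(0)|.
λ_max is located by doubling then 60 bisection steps — deterministic and
scale-aware (rescaling y rescales weights, not the boundary).  The winning
λ minimizes mean held-fold MSE in a 10-fold cross-validation on the other
video set, with folds formed as contiguous blocks of the fixed condition
order (deterministic without a seed); ties go to the smallest λ.

Generalization is r_CV: Pearson correlation between Xw predictions and
actual responses over the 60 held-out conditions.  Screening requires
r_CV > 0 with q < 0.01 in both sets, where one-sided p-values come from
the exact t-transform of a Pearson correlation with n = 60 and
Benjamini–Hochberg correction runs across voxels within each set.  The
t-transform is a documented choice — the screening contract specifies FDR
correction but not the p-value construction.

A note on weight recovery: because responses are generated from the raw
design but fit on z-scored columns, the fitted weights live in the
standardized basis; recovery is therefore assessed against the planted
tuning multiplied elementwise by the column standard deviations.

### Correlation-distance k-means and d′

Profiles are row-centered and unit-normalized, so the distance to a
centroid is 1 − Pearson r and clustering is invariant to per-voxel offset
and positive gain.  Lloyd iterations run for up to 500 iterations × 10
random-initialization replicates; the lowest total within-cluster
correlation distance wins.  Rows with standard deviation below 1e-10 are
excluded up front and labeled 0.  An empty cluster is re-seeded at the
point farthest (in correlation distance) from its assigned centroid.

Cluster-count diagnostics report, per k in 2..20, the mean silhouette
under the correlation metric and the mean pairwise centroid correlation.
The helper `choose_k` picks the maximal-silhouette k among those whose
centroid similarity stays below 0.8 (config-exposed; both criteria were
combined qualitatively in the original procedure, so the threshold is a
formalized stand-in).

Co-assignment d′ between two partitions: over all unordered voxel pairs,
Hit = P(together in B | together in A), FA = P(together in B | apart in
A), d′ = z(Hit) − z(FA).  Counting goes through the A×B contingency table
(O(N + k²)), which is exactly equivalent to pair enumeration and makes
50,000-voxel baselines cheap.  Degenerate rates are clamped to 1/(2P)
from the boundary with P the total pair count — on the worked 4-voxel
example (A = [1,1,2,2], B = [1,2,1,2]) this gives Hit = 1/12, FA = 1/2,
d′ ≈ −1.383.  If all pairs are together (or all apart) in A, a
conditioning set is empty and the statistic is undefined (error).  The
shuffled baseline permutes the voxel order of one labeling, recomputing d′
per shuffle; its expectation is zero and its spread shrinks with voxel
count.

Centroids of equal-k solutions are matched one-to-one by Hungarian
assignment on the pairwise correlation matrix.  Colors come from
classical (Torgerson) MDS of the centroid correlation-distance matrix to
3 dimensions, each axis min-max rescaled to [0, 1] as an RGB channel;
axes whose spread is negligible relative to the embedding scale (degenerate
eigenvalues) map to 0.5.

### Gist descriptors

Frames are resized to 256×256, mean-removed, and local-contrast
normalized (division by a Gaussian-pooled local energy estimate, which
makes the descriptor invariant to frame-wide luminance offsets).  The
filter bank holds single-lobe (analytic) log-Gabors in the frequency
domain — Gaussian in log radial frequency, Gaussian in direction — at 4
scales (center frequencies 64/32/16/8 cycles per image) with 12/8/6/4
orientations fine-to-coarse.  The printed layout in the source analysis
lists orientation counts (12, 8, 6) alongside "4 spatial frequencies and
scales" and a 1,920-D output; since 1,920 / 64 grid cells = 30 filters and
12+8+6 = 26, the only consistent layout is a 4-scale, 30-filter bank, and
that is the (config-overridable) default.  The bank is jointly normalized
so its summed squared transfer never exceeds 1, giving a Parseval-style
bound (total filter energy ≤ image spectral energy).  Power is the mean
squared response magnitude per 8×8 grid cell, ordered cells-row-major
within filter, filters fine-to-coarse, for 30 × 64 = 1,920 dimensions.
Frame descriptors are pooled over all videos, reduced by PCA, and the
first 20 component scores averaged within video.

### Preference maps

Given two per-voxel r_CV maps, the winner is the larger value and the
strength the absolute margin; exact ties get a tie code with strength 0,
and voxels missing either value are dropped with a logged count.  The
gist-vs-features comparison runs on within-set reliable voxels (better
early-visual coverage); involvement-vs-visibility runs on across-set
reliable voxels.

## The synthetic study

The generator emulates the study conditions end to end with planted
ground truth:

- **Ratings.**  Each of the 60 actions draws an archetype from a small
  library of seven (body-prototype, target-prototype) pairs — fine
  manipulation, coarse object handling, upper-body near-space action,
  whole-body locomotion, person-directed, actor-directed, seated
  observation — plus per-action jitter; the two exemplar videos of an
  action perturb the prototype independently (sd 0.05), so the sets
  correlate strongly but not perfectly.  12 raters (the experiments used
  9–12 per video) give independent Bernoulli responses around the
  prototypes.  Prototypes are sharp (baseline 0.02, peaks ≥ 0.9),
  reflecting the high rater agreement real ratings show; with these
  settings the averaged body ratings compress to ~7–8 components at 95%
  variance and targets to ~4–5, mirroring the 7 + 5 structure of the
  reference data.  Target prototypes get larger per-action variation
  (sd 0.15) because the five target questions vary more independently
  across actions than body parts do.  Visibility prototypes are a damped
  copy of involvement plus a visibility baseline and independent noise
  (involved features are usually but not always visible, and vice versa),
  putting the involvement–visibility correlation around 0.5–0.6.
- **Voxel responses.**  A configurable fraction (default 30%) of voxels
  are pure noise; the rest split evenly among K = 5 networks.  Network
  tunings are unit-norm Gaussian vectors over the design columns; each
  voxel adds Gaussian jitter with sd 10% of the tuning norm, making
  within-network profiles similar but not identical.  Responses are
  design · tuning + Gaussian run noise, drawn independently per split and
  set; run-noise sd defaults to 0.5× the voxel's across-condition signal
  sd, which fixes the expected within-set split-half reliability of
  signal voxels at 1/(1 + 0.5²) = 0.8 (the planted-attenuation closed
  form σ²_sig/(σ²_sig + σ²_noise)), with noise voxels near zero — a
  bimodal approximation to the empirical reliability distribution that
  reproduces the qualitative rise-then-plateau curve shape.  No published
  per-voxel noise magnitudes exist to calibrate against, so these
  defaults target curve shape, not level.
- **Frames.**  Half the videos are full-field drifting gratings with
  orientation and spatial frequency drawn from the gist bank's lattice;
  half are Gaussian blobs with jittered positions.  All parameters are
  recorded for test assertions.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: hemodynamics and temporally correlated noise,
spatial autocorrelation between neighboring voxels, graded (rather than
bimodal) reliability, voxels tuned to image statistics rather than rated
features, anatomical geometry, and inter-subject variability.  Synthetic
r_CV values are correspondingly higher than typical group-data values.

## Problem sizes

Tests and the acceptance script run the pipeline at a few hundred to a
few thousand voxels and the d′ baseline at 50,000 voxels; these sizes
were chosen to exercise every code path at stable statistics while
keeping a full run on a single CPU in the low minutes.  The end-to-end
pipeline at its defaults (2,000 voxels, 120 videos) completes in well
under ten minutes on one CPU.

## Known limitations

- The plateau tolerance (5% of range) and the k-selection centroid-
  similarity threshold (0.8) formalize procedures that were originally
  applied qualitatively; both are config-exposed.
- k-means replicate behavior mirrors the usual best-of-replicates
  contract but is not bit-matched to any particular external
  implementation.
- Real-data mode expects the package's own documented CSV/NIfTI layout;
  an adapter for a specific public deposit must map that deposit's file
  layout onto `read_ratings_csv` / `read_response_set` inputs.
- Variance partitioning between feature spaces is deliberately not
  implemented (unstable on this class of data); preference maps are the
  supported comparison.
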