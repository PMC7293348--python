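# actionenc

Voxel-wise encoding models and data-driven network clustering for
condition-rich fMRI studies of visual action perception.

## The problem

When people watch short videos of everyday actions (knitting, running,
shaking hands, ...), much of occipito-temporal and parietal cortex responds
differentially across actions.  This package implements the analysis chain
used to characterize that structure:

1. **Reliability-based voxel selection.**  Each voxel's split-half
   reliability is the Pearson correlation of its 60-condition response
   vector between odd and even runs (within a video set, or across the two
   sets, which requires generalization over exemplar videos of the same
   action).  A cutoff is chosen where the mean *item-pattern reliability*
   (split-half reliability of each stimulus's multi-voxel pattern) begins
   to plateau: stricter cutoffs past that point shrink coverage without
   buying reliability.
2. **Feature spaces from behavioral ratings.**  Online raters mark the 20
   body parts engaged by each action and answer 5 yes/no questions about
   the action's target (object, another person, the actor, near space,
   far space).  Averaged ratings are reduced by PCA, keeping components up
   to 95% cumulative variance, and the body-part and target scores are
   concatenated into the design matrix (7 + 5 = 12 columns on the
   reference data).
3. **Ridge encoding models.**  Each voxel's response magnitude is modeled
   as y = Xw with an L2 penalty λ‖w‖².  λ is selected per voxel from 100
   candidates (0 up to the largest λ yielding a non-null model) by 10-fold
   cross-validated MSE on the *other* video set; generalization is scored
   as r_CV, the correlation between predicted and actual responses for the
   held-out set.  Voxels are kept when r_CV > 0 with FDR-corrected
   q < 0.01 in both sets.
4. **Network clustering.**  Voxel weight profiles (or raw response
   profiles) are grouped by k-means under the correlation distance; k is
   guided by silhouette and centroid-similarity diagnostics.  Robustness
   across video sets is quantified by the co-assignment sensitivity index
   d′ = z(Hit) − z(FA) over all voxel pairs, against a shuffled-label
   baseline whose expectation is zero.  Centroids are matched across sets
   by Hungarian assignment, colored by a 3-D classical MDS embedding of
   their correlation distances, and back-projected through the PCA
   loadings onto the original 25 rated features.
5. **Gist descriptors and preference maps.**  A 30-filter oriented
   log-Gabor bank (4 scales; 12/8/6/4 orientations) pooled on an 8×8 grid
   yields 1,920-D frame descriptors, reduced to 20 PCs per video, for
   comparing low-level scene structure against the rating-based features
   with winner-take-all preference maps (winner = larger r_CV, strength =
   the margin).

A synthetic-data generator produces every input the pipeline consumes —
per-rater binary ratings around archetype prototypes, voxel responses
driven by planted network tunings plus Gaussian run noise, and grating /
blob video frames — so each stage is testable against known ground truth.

## Worked example

```python
import numpy as np
import actionenc as ae
from actionenc.synthetic import BODY_PARTS, TARGETS

cfg = ae.SyntheticConfig(n_voxels=800, seed=1)
ratings = ae.generate_ratings(cfg)
inv = ratings["involvement"]
body = ae.average_ratings(inv.body, list(BODY_PARTS), inv.video_ids)
target = ae.average_ratings(inv.target, list(TARGETS), inv.video_ids)
design = ae.combine_spaces(ae.fit_pca(body, 0.95), ae.fit_pca(target, 0.95))
print("retained components:", design.values.shape[1], "(body + target)")

design_by_set = {1: design.values[:60], 2: design.values[60:]}
data, truth = ae.generate_voxel_responses(cfg, design_by_set)

rel = ae.reliability_curve(data, scheme="within_set")
cutoff = ae.select_cutoff(rel.curve)
reliable = rel.surviving(cutoff)
print(f"plateau cutoff r >= {cutoff:.2f}, {reliable.sum()} reliable voxels")

fits = ae.fit_encoding(design_by_set,
                       {s: data.split_average(s)[reliable] for s in (1, 2)})
print(f"median r_CV (train set 1): {np.nanmedian(fits[1].r_cv):.2f}")

inc = fits[1].included_mask
sol1 = ae.kmeans_correlation(fits[1].weights[inc], 5, seed=0)
sol2 = ae.kmeans_correlation(fits[2].weights[inc], 5, seed=0)
dp = ae.coassignment_dprime(sol1.labels, sol2.labels)
base = ae.shuffled_baseline(sol1.labels, sol2.labels, n_shuffles=100, seed=0)
print(f"cross-set d' = {dp.dprime:.2f}, "
      f"shuffled baseline = {base['mean']:.3f} (sd {base['sd']:.3f})")
gt = truth.network_label[np.flatnonzero(reliable)[inc]]
print(f"d' vs planted networks = "
      f"{ae.coassignment_dprime(gt, sol1.labels).dprime:.2f}")
```

Output:

```
retained components: 11 (body + target)
plateau cutoff r >= 0.30, 560 reliable voxels
median r_CV (train set 1): 0.93
cross-set d' = 4.73, shuffled baseline = 0.000 (sd 0.009)
d' vs planted networks = 5.09
```

Reading the numbers: the averaged ratings compress into 11 principal
components; the plateau rule lands at a cutoff of r ≥ 0.30 and keeps
exactly the 70% of voxels that carry planted signal; the encoding model
predicts held-out-set responses well (median r_CV 0.93 — this synthetic
condition is less noisy than typical group fMRI data); the 5-network
partitions of the two video sets agree far above the shuffled-label
baseline of zero, and match the planted network labels.

The same analysis runs end-to-end from a config with
`actionenc run-all --seed 1 --out out/` (see `actionenc --help` for
per-stage subcommands), writing NIfTI maps, CSV tables and a provenance
manifest.

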