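# Methods

This note documents the statistical models the package implements, the
synthetic study it validates them on, and the numerical and design choices
that were genuinely open.

## Selectivity maps and cluster-level inference

The category contrast at a voxel is β(category) − mean of the other five
categories' β. Single-subject maps test this contrast across runs with a
one-sample *t* (df = n_runs − 1); group maps test subjects' run-averaged
contrasts (df = n_subjects − 1). Voxels with zero sample variance have no
defined *t*; they are flagged and excluded from thresholding rather than
silently set to 0.

Cluster-level correction is nonparametric. Suprathreshold voxels (one-sided
*t* above the threshold, default *p* < 0.001 at the map's df) are grouped
into connected components — 18-neighbour connectivity by default, the usual
volumetric convention, configurable to 6 or 26. The null distribution of the
**maximum** cluster size is built by sign-flipping the observation-level
contrast maps (runs, or subjects for group maps): under the null the
contrast is symmetric about zero, so sign flips are exchangeable. All 2^n
sign patterns are enumerated when that is no more than `n_perm` (so 8-run
subject maps are exact); otherwise `n_perm` patterns are sampled. Each
observed cluster gets p = max(#{perm max ≥ size}, 1)/n_perm and
Benjamini–Hochberg selects survivors at the cluster α. This targets the same
error control as parametric random-field cluster correction without its
smoothness assumptions, at sizes where the permutation loop is cheap.

The **overlap index** between two categories' surviving voxel sets is
|A ∩ B| / min(|A|, |B|). An empty set is an explicit error
(`EmptyClusterError`), not an index of 0, because "no significant
activation" is a qualitatively different finding that must be reported as
such. The *visual mask* restricts analysis to visually responsive cortex:
voxels whose all-conditions mean β is positive at a liberal one-sided
*p* < 0.05, intersected with an anatomical mask.

## Vector-of-ROIs

Anchors are configuration, not code: an ordered list of named mm
coordinates. A cubic interpolating spline (chord-length parameterized;
order degrades gracefully below four anchors) is re-parameterized by arc
length on a dense piecewise-linear resampling (10⁴ points — closed-form arc
length does not exist for cubic splines; the resampling keeps the spacing
error far below 0.01 mm). Sphere centres run from the first endpoint every
`spacing_mm` (default 3) up to the last point on the curve; each sphere has
`radius_mm` (default 6), so neighbours overlap. A voxel belongs to a sphere
iff its centre (0-based index mapped through the affine) lies within the
radius. Per sphere and subject the run-averaged β of each condition is
averaged over member voxels; the normalized β subtracts the across-condition
mean, so the six values sum to zero. Spheres with fewer than two valid
voxels are missing and propagate as missing — never as zero — into every
downstream statistic.

**Peak analysis and circularity.** The peak is the sphere with the maximal
group-mean normalized β for a category within a region; the preferred
condition is then compared with the other five by paired two-tailed
*t*-tests, Bonferroni-corrected for the five comparisons. Selecting the peak
on the same data that feeds the tests inflates them badly: simulation at 18
subjects × 34 (spatially smoothed) spheres puts the family-wise type-I rate
near 0.26 instead of 0.05, and leave-one-subject-out selection is just as
inflated because the selection still shares noise with every test subject.
`peak_analysis` therefore accepts independent `selection_profiles`; the
pipeline selects peaks on the odd runs and tests on the even runs, which
simulation confirms is calibrated (≈ 0.04). Calling it without selection
profiles reproduces the descriptive same-data variant.

## Representational similarity analysis

Neural RDMs are Pearson correlations of condition patterns (sphere voxels or
layer units); a zero-variance pattern is an error naming the condition.
Model RDMs: **animacy** and **action** from 1–7 ratings as pairwise absolute
differences — at category level, the mean over cross-category stimulus
pairs, which collapses to the difference of category means when ratings are
noiseless; **shape** as pairwise differences of category-mean aspect ratios.

The **aspect ratio** is P²/(4πA) on the binary stimulus mask: area is the
foreground pixel count; perimeter is the marching-squares contour length
after Gaussian pre-smoothing of the mask (σ = 1 px). The smoothing matters:
on the raw binary image the contour hugs the rasterization staircase and
overestimates a circle's perimeter by ~11%, while σ = 1 px recovers the
isoperimetric value 1.0 within 1% and keeps squares and 4:1 rectangles
within 2–3% of 4/π and 6.25/π at any orientation.

Model–brain fit is the Pearson correlation of the 15 lower-triangle entries
(diagonal excluded), after converting neural similarity to dissimilarity as
1 − r so its sign convention matches the model distances. The sources we
follow do not state that sign convention explicitly; `rsa_correlate` exposes
it as a switch (`neural_to_dissimilarity`), and flipping it only negates the
fit. Per-sphere group inference is a two-sided one-sample *t* on Fisher-z
fits, Bonferroni-corrected for the number of spheres. The **noise-ceiling
lower bound** is the mean over subjects of the correlation between each
subject's lower triangle and the average of the remaining subjects'.
Along-vector couplings between two models' fit profiles are per-subject
Pearson correlations across spheres (missing spheres pairwise-deleted, at
least three shared required), tested on Fisher-z values with Bonferroni
m = 3. The model-orthogonality report (`model_rdm_correlations`) prints the
pairwise lower-triangle correlations between model RDMs so near-zero values
can be verified for any concrete stimulus set.

**MDS** is classical Torgerson scaling: double-centre the squared distances,
eigendecompose, scale the top eigenvectors by √eigenvalue. The
non-Euclidean warning fires when negative eigenvalue mass exceeds half the
positive mass; note the double-centred Gram matrix has non-negative trace,
so negative mass can never exceed half of the *total* — a threshold on the
total would be dead code.

## Effector and grasp indices

effector(bp) = r(bp, tools) − r(bp, manipulable);
grasp(bp) = r(bp, manipulable) − r(bp, non-manipulable), computed on raw
Pearson similarities per their definition (a Fisher-z variant sits behind
`fisher=True`). They telescope exactly: effector + grasp =
r(bp, tools) − r(bp, non-manipulable). Along the vector, per-sphere group
*t*-tests are Bonferroni-corrected for the number of spheres; the
index–activation coupling correlates a body part's index profile with a
category's normalized activation profile per subject (Fisher-z group *t*,
Bonferroni m = 6, one test per category).

## Unit sheets

Unit selectivity is a two-sample pooled-variance *t* over stimuli (12
category stimuli vs. the other 60, df = 70), selective iff *t* > 3.5. The
pooled (rather than Welch) variance matches the plain category-vs-all
contrast; with 12 vs. 60 stimuli of equal nominal variance the two differ
negligibly. Top-k profiles rank units by *t* with ties broken by ascending
unit id for determinism.

The **section overlap score** tiles the sheet into 1 mm squares (a unit
belongs to exactly one section; empty sections are excluded — they carry no
information about co-occurrence), computes each category's per-section
selective fraction, and maps the Pearson correlation of two categories'
fraction vectors to (r + 1)/2. This satisfies the three defining endpoints:
1 for identical selectivity maps, 0 for perfectly complementary ones, 0.5
when one category's presence carries no information about the other.

**Permutation inference.** `permutation_test` shuffles stimulus-to-category
labels and recomputes an arbitrary statistic; one-sided
p = max(#{perm ≥ obs}, 1)/n_perm, so the floor is 1/n_perm (0.0001 at the
conventional 10,000 shuffles). Shuffles on which the statistic is undefined
are tracked and the test aborts beyond 10%. For the **overlap contrast**
(is the score of one category pair higher than another's, averaged over
model instances?) label shuffling is the wrong null: it destroys all
category tuning, so on any clearly tuned sheet no unit passes *t* > 3.5
under the shuffle and the score is undefined essentially always. The
default null therefore shuffles each sheet's unit-to-**position** assignment
instead — selectivity is preserved while its spatial arrangement is broken,
which is exactly the exchangeable null for a spatial co-occurrence
statistic. Note what this implies: co-occurrence carried at the *unit* level
(single units selective for both categories) survives position shuffling
and is correctly treated as baseline, so the contrast detects spatial
co-clustering beyond unit-level co-tuning. The label-shuffle scheme remains
available (`scheme="labels"`) and aborts with diagnostics when selectivity
collapses.

## The synthetic study

The generator emulates the structure of a category-topography fMRI study:
18 subjects × 8 runs × 6 conditions (faces, bodies, hands, tools,
manipulable, non-manipulable) of beta volumes on a 3 mm isotropic grid with
a diagonal affine, written as standard NIfTI-1 so real beta maps are
drop-in replacements. Each condition's noiseless signal is one isotropic
Gaussian blob; runs differ only by i.i.d. voxelwise Gaussian noise. Default
layout along the 99 mm gradient axis (34 spheres at 3 mm spacing):
non-manipulable 25 mm, faces 33, manipulable 50, tools 75, hands 81, bodies
90; blob σ 9 mm for body parts and 15 mm for objects; amplitudes 1.0; run
noise sd 0.25. The hands–tools separation of 6 mm makes their selective
clusters overlap; the object ordering along the axis produces
tools > manipulable > non-manipulable at the lateral object peak and the
reverse ventrally; the noise level was set from a power analysis of the
weakest recovery statistic (the effector-index group *t*, which depends on
within-sphere pattern correlations) and then left alone.

Ratings are clipped Gaussians on the 1–7 scale around per-category means
(action defaults: hands 6.3, tools 5.7, bodies 4.5, faces 3.4, manipulable
3.3, non-manipulable 2.9; animacy defaults are synthetic: body parts ~6.5,
objects ~1.6). Clipping bias is negligible at sd ≤ 1. Stimulus masks are
rasterized ellipses and rectangles on a 400 × 400 px canvas; rectangles use
an exact half-open pixel-centre test so an axis-aligned h × w rectangle
covers exactly h·w pixels.

Unit sheets place units uniformly on a 50 × 50 mm sheet. In **null** mode
each unit is tuned to each category independently (probability 0.05,
amplitude 5 × the response sd). Those defaults are load-bearing: the
amplitude keeps tuned units above the *t* > 3.5 call even when co-tuned to a
second category (co-tuning inflates the pooled variance of the vs-all
contrast and would otherwise suppress detection, inducing negative
dependence between categories' realized selectivity maps), and the sparsity
makes triple co-tuning negligible — so realized selectivity maps really are
independent across categories, which is what makes 0.5 the chance overlap
score. In **clustered** mode a unit is tuned to a category iff it lies
within that category's planted disc, so coincident discs give identical
selectivity maps and an overlap score of exactly 1.

What the generator does *not* emulate: haemodynamics and temporal structure
(the pipeline consumes beta maps by declared scope), anatomy (the grid is a
box; group analyses assume a shared grid, which synthetic subjects satisfy
by construction), inter-subject spatial variability, spatially correlated
noise, and network training dynamics. Passing recovery tests therefore
demonstrates that the estimators recover planted structure at realistic
sizes and noise — not that real cortical data meet the estimators'
assumptions.

## Validation battery and problem sizes

`tests/test_acceptance.py` runs, at sizes chosen to keep the default suite
in the minutes range on one CPU:

- analytic conventions: permutation floor 1/10,000 = 0.0001; Bonferroni
  0.05/34 (prints as 0.0014) and 0.05/6 (0.0083);
- chance baseline: 100 null sheets (2,500 units) give a mean hands–tools
  section-overlap score within 0.02 of 0.5;
- oracle equivalence: overlap index exact against brute-force set
  intersection on 1,000 random cluster pairs; RDM constructions and
  `rsa_correlate` within 10⁻¹² of naive reimplementations on 100 random
  inputs;
- closed forms: aspect ratio of circle/square/4:1 rectangle within 2–3% of
  1.0, 4/π, 6.25/π; MDS round-trip Procrustes error < 10⁻⁶; the
  effector+grasp telescoping identity to 10⁻¹⁴;
- calibration: the permutation test and each Bonferroni family (peak m = 5
  with split-half selection, model-pair m = 3, index profile m = 34,
  index–activation m = 6) hold family-wise type-I ≤ 0.05 within binomial
  tolerance over 500 null replicates (the generic permutation test is also
  checked at 2,000 replicates in the unit tests, with n_perm = 199 — the
  p-value's validity does not depend on the number of shuffles);
- recovery at 18 subjects and default SNR, 100 seeds each: lateral/ventral
  object-ordering recovery at split-half-selected peaks; a significantly
  positive lateral hand effector index with the face index not
  systematically positive; overlap index exactly 1.0 for a planted
  manipulable-inside-tools nesting; positive hands–tools overlap for blobs
  6 mm apart at σ = 9 mm, SNR 2; and a noise-ceiling lower bound that rises
  monotonically toward 1 over a 3-point noise grid (50 seeds per point).

`scripts/acceptance.py` recomputes the chance-baseline quantity from
scratch at the full 100-sheet size; every random draw descends from the
`--seed` argument through a `numpy` `SeedSequence`.

## Known limitations

- Group cluster analysis assumes a shared voxel grid; real multi-subject
  data must be normalized upstream.
- The cluster-size permutation null assumes sign-symmetric contrasts under
  the null; strongly skewed run-level noise would violate it.
- Category-level rating RDMs default to the mean of cross-category pairwise
  distances; distances between category means are available but differ for
  noisy ratings.
- The section-overlap score inherits Pearson correlation's sensitivity to a
  few dense sections when unit density is very non-uniform.
- Same-data peak selection remains available for descriptive use; its
  *t*-tests must not be read as calibrated inference.
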