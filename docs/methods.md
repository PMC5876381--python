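# Methods

This note documents the models, numerical choices and known limitations
behind `eitbladder`. It is the package's own account of its science; every
number quoted here is recomputed by the test suite or by
`scripts/acceptance.py`.

## Problem

Non-invasive bladder-state monitoring for people with urinary
incontinence: a belt of 32 electrodes around the pelvis injects small
currents (5 mA peak, skip-4 pattern) and measures boundary voltages. A
supervised classifier decides from one voltage *frame* (928 differential
measurements) whether the bladder is **full** (volume at or above a
threshold, default 300 ml) or **not full**. No image reconstruction is
involved; classification operates directly on the frame.

## Forward model

### Geometry

The pelvic domain is an elliptical cylinder with a mid-height ring of 32
evenly spaced electrodes (electrode 0 on the anterior midline, indices
counter-clockwise). Default horizontal semi-axes are 170 x 110 mm (male)
and 180 x 120 mm (female), height 200 mm; boundary variants scale the
anterior-posterior semi-axis only (x0.90 .. x1.10 in the main grid,
x0.85/x0.95/x1.05/x1.15 in the withheld grid). These absolute sizes are
package defaults chosen to be anatomically plausible at CT-like
proportions; classification depends on relative contrast, not absolute
scale.

The bladder is an axis-aligned ellipsoid. Its semi-axes keep fixed
aspect ratios (axial : coronal : sagittal = 1.2 : 1.0 : 0.9) and are
scaled so the ellipsoid volume equals the requested urine volume
exactly ("ellipsoid-consistent" model); the model is pluggable for users
with their own radii-vs-volume regressions. The *bottom* of every
bladder is fixed at one axial semi-axis of the 240 ml bladder below the
domain centroid, so a filling bladder ascends into the abdomen; the
centre sits halfway between the domain centroid and the anterior wall.

### Meshes and FEM

Two domains are supported.

* **2-D electrode-plane reduction** (default for the large factor
  grids): the domain cross-section with the *exact* ellipse obtained by
  slicing the placed ellipsoid at the electrode plane. Triangulated by
  Delaunay over a graded point set — boundary nodes, inclusion-boundary
  nodes, a refined annular band along the electrode boundary (the
  inter-electrode fields are steep) and hexagonal interior lattices,
  ~1,800 nodes at default density. The triangulation conforms to the
  inclusion curve, so the tagged area matches the analytic slice area
  to well under 5%.
* **3-D elliptical cylinder** (default for the TC1-scale experiments):
  a graded in-plane triangulation extruded into conforming tetrahedra
  (prisms split 3-ways with the smallest-global-index diagonal rule),
  z-layers refined across the bladder's vertical extent, elements
  tagged by centroid (tagged volume within ~2% of the nominal volume at
  default density, ~17k nodes).

The conduction equation `div(sigma grad u) = 0` is discretised with
first-order simplices; background conductivity 0.2 S/m (weighted pelvic
soft-tissue average), bladder at the urine conductivity (0.5-3.5 S/m;
the thin bladder wall is neglected). Electrodes are point electrodes by
default (one boundary node each); a shunted small-patch model is
available via `patch_frac > 0` (boundary nodes within that fraction of
the inter-electrode interval tied to one unknown), at the cost of
slower mesh convergence from the square-root current singularity at
patch edges. One interior node near the centroid is grounded;
differential measurements
are reference-independent. Each conductivity map is factorised once
(sparse LU) and all 32 injections solved as one block. Solver checks:
reciprocity to 1e-6 relative, conductivity scaling (`sigma -> k sigma`
implies `u -> u/k`) to 1e-8, frame change < 1% under 2x mesh
refinement.

A skip-4 pattern on 32 electrodes injects through pairs `(i, i+5)`;
measurement pairs use the same offset and the three pairs touching an
injection electrode are discarded: 32 x 29 = 928 retained measurements,
ordered injection-major then by leading measurement electrode, polarity
`u(first) - u(second)`.

### Limitations of the 2-D reduction

The electrode-plane reduction preserves ascension (through the slice
radii), volume monotonicity and conductivity contrast, but it sees only
the in-plane footprint: an ellipsoid that does not reach the electrode
plane (the 20 ml withheld volume) produces a background-only frame,
invisible at every conductivity. This is the main known divergence from
the full 3-D model and is why the withheld-grid linear-SVM accuracy
runs ~5 points below its 3-D-based reference value (see "Reproduction
experiments").

## Noise model

Noisy replicates are `u_i + max|u| * eta_i` with Gaussian `eta`. Three
modes:

* **per-channel** (default): `sd_i = |u_i| * 10^(-SNR/20)`. Every
  channel carries the stated SNR and the expected frame L2 SNR
  (`20 log10(||u|| / ||noise||)`) equals it identically. This matches
  how EI measurement-device SNRs are specified and reproduces the
  reference study conditions (perfect separability at 60/80 dB,
  monotone degradation).
* **frame-uniform**: i.i.d. noise with one sd for all channels,
  referenced to `max|u|` and calibrated to the frame L2 SNR. Under this
  reading the many low-amplitude channels drown after standardisation
  and cosine-KNN misclassifies whole volume levels even at 60 dB; it is
  retained for comparison.
* **eq-literal**: the Gaussian *density* evaluated at `u_i` with
  uniformly random mean and sd on `(0, 10^(SNR/20)]` - a smooth warp,
  not white noise; retained because the published formulation is
  ambiguous, with this documented reading.

Replicates use distinct seeded sub-streams; empirical frame SNR is
calibrated within +-0.5 dB over ensembles.

## Datasets, labels, folds

Volumes: 40:40:280 ml ("not full") and 300:20:420 ml ("full"), split at
300 ml. Conductivities: 13 levels at 0.25 S/m steps from 0.5 S/m (the
study's factor table counts 13 levels and its totals require it; a
13-level 0.25-step grid from 0.5 runs to 3.5 S/m). Test cases: TC1
varies volume only (1.75 S/m, male boundary, 99 noisy frames per ideal
frame), TC2 adds conductivity (39), TC3 adds six boundaries (9); each at
SNRs {20, 40, 60, 80} dB, giving 1,400 / 7,280 / 10,920 observations per
SNR. The withheld TC4 grid shares no factor value with TC3: volumes
20:40:260 + {295, 299, 301, 305} + 310:20:430 ml, conductivities
0.625:0.25:3.125, boundaries +-5%/+-15%, SNRs {30, 50, 70} dB; the
builder verifies disjointness before simulating. A threshold-variant
grid shifts all TC3 volumes +60 ml and labels at 360 ml.

Folds are stratified: each class is shuffled once (seeded) and split
into 10 disjoint test sets (remainders to the earliest folds); training
sets are the complements, so every observation is tested exactly once.

## Classifiers and metrics

Frames are standardised per predictor (mean/sample-sd of the training
fold only; constant predictors flagged and left at scale 1). Linear SVM
(hinge/SMO, C = 1), cubic SVM (polynomial kernel `(x.x'/p + 1)^3`,
`p` = number of predictors, C = 1) and cosine 10-NN (uniform votes; ties
resolve to "not full" via the class coding). Sensitivity is the correct
rate on "full", specificity on "not full", accuracy their mean (balanced
accuracy); aggregates are mean +- sample sd over the 10 folds.
Misclassification histograms count errors per factor level, averaged
over the fold classifiers and expressed as percent of test size, so a
histogram sums to the overall misclassification percentage. A
two-threshold report (default 240/360 ml) quantifies confidence outside
an uncertainty band.

## Reproduction experiments and problem sizes

`eitbladder.experiments` fixes the desk-scale problem sizes used by the
tests and by `scripts/acceptance.py`: TC1 keeps 99 noisy frames (3-D
forward model, 14 meshes); TC2 runs with 9 and TC3 with 3 noisy frames
(2-D reduction); TC4 thins the withheld grid to 6 conductivities, 4
boundaries and 2 noisy frames per ideal frame and SNR; the 360
ml-threshold variant uses the TC3 sizes. Replicate counts scale the
ensemble, not the physics; measured accuracies at these sizes track the
full-size study within a few points.

Behaviour at these conditions (seeds vary the last decimals):

* TC1: 100%/100% for all three classifiers at 60 and 80 dB; at 20 dB
  the linear SVM error is ~1-2% (reference study: 9.71%) with errors
  concentrated at 240-300 ml.
* TC2 at 20 dB: misclassification per conductivity peaks below 1 S/m
  and stays under ~3% of test size.
* Accuracy floor over classifiers x TC1-3 x SNRs: ~83.5-84.5%
  (reference 84.94 +- 1.28%); TC3 at 40 dB puts the linear SVM and
  cosine KNN below 94%, as reported.
* TC4: all three classifiers land at 72-79% overall accuracy depending
  on seed, with heavy misclassification at the near-threshold probes
  (roughly 50-72% at 295/299 ml, ~30% at 301/305 ml). The reference
  values for cosine KNN (79.98%) and cubic SVM (73.16%) are matched
  within a few points, but the study's Linear > Cosine > Cubic ordering
  and the linear SVM's 81.66% are not robustly reproduced: the 20 ml
  withheld scenario is invisible to the 2-D reduction (background-only
  frame at every conductivity), so its classification is essentially
  arbitrary and seed-dependent, and it drags the transfer accuracies.
  The near-threshold misclassification structure - the study's central
  TC4 finding - reproduces closely.
* Threshold variant: accuracies within ~1-1.5 points of the TC3 20 dB
  values, supporting threshold-independence of the approach.

### Other numerical notes

* Cosine distance discards magnitude; after standardisation the volume
  signal is nearly one-dimensional, so frames of the volume closest to
  the dataset-mean crossing (~240-280 ml here) have weakly determined
  direction. This makes cosine-KNN errors land just *below* the
  threshold in this geometry, where the reference study reports them
  just above; the crossing location depends on the (unpublished)
  radii-vs-volume regression and is not recoverable from the printed
  information.
* On the high-SNR plateau of the large grids, residual errors are
  geometry collisions (distinct factor tuples with near-identical
  frames in the reduction), not noise; accuracies there can jitter by
  ~0.2 points between 60 and 80 dB.
* All randomness flows from explicit seeds (dataset builders spawn one
  sub-stream per scenario, one per replicate); pipelines are
  bit-reproducible for a fixed seed.
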