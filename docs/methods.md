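# Methods

`neurorsa` implements a spatio-temporal representational-similarity
analysis (RSA) pipeline for comparing time-resolved sensor recordings
(MEG-style), spatial activation patterns (fMRI-style) and layered-model
activations, together with a synthetic-data generator that makes every
stage testable end to end without access to recordings.

## Representational dissimilarity matrices

All analyses abstract each signal space into representational
dissimilarity matrices (RDMs): for `n` conditions, the condensed vector
of `n(n-1)/2` pairwise dissimilarities in lexicographic `(i < j)` order.
The diagonal is undefined and never stored.  Two metrics are
implemented:

* **Correlation distance** (`1 − Spearman's R`, bounded [0, 2]) between
  condition pattern vectors — used for voxel patterns and model-layer
  activations.  Ranks use average-tie handling.  A constant pattern
  vector makes the rank correlation undefined; such entries are stored
  as NaN, counted and logged, and excluded pairwise downstream — never
  silently zeroed.
* **Pairwise decoding accuracy** (percent, bounded [0, 100]; chance =
  50) between two conditions' trial sets at one timepoint.  The `M`
  trials per condition (default 30) are sub-averaged in randomly
  assigned groups of `k = 5` into `L = M/k` pseudo-trials; a linear
  maximum-margin classifier (SVM, `C = 1`, no additional feature
  scaling) is cross-validated leave-one-pseudo-trial-out over the `L`
  folds; the whole procedure is repeated (default 100 times) with fresh
  assignments and the mean test accuracy is the RDM entry.  Trials not
  divisible by `k` are dropped uniformly at random per repetition and
  logged.  The default solver path calls the bundled libsvm binding
  directly; `engine="sklearn"` routes through `sklearn.svm.SVC` and
  produces identical accuracies (same solver) — the fast path only
  skips per-call input validation, which dominates at 10-sample fits.

  On exchangeable (null) data this estimator is centred slightly below
  50% (measured grand mean ≈ 48.4% over 200 datasets), the familiar
  pessimistic bias of leave-one-out cross-validation; per-dataset
  expected accuracy scatters with SD ≈ 11% because the finite trial
  sample fixes an empirical geometry that repetition averaging cannot
  remove.

* **PCA-balanced summary RDM**: each layer's condition-by-unit matrix
  is centred and reduced to `n_conditions − 1` principal-component
  scores (117 for the 118-condition design) so every layer contributes
  an equal-width block regardless of unit count; blocks are
  concatenated (117 × 8 = 936 dimensions) and passed to the
  correlation metric.  Each block is scaled to unit Frobenius norm —
  this is what makes the balancing effective and the summary invariant
  to rescaling any single layer; components are *not* whitened
  individually, so within-layer variance structure is preserved.
  Component signs follow the largest-|loading|-positive convention;
  layers with fewer units than components are zero-padded to fixed
  width.

RDM pairs are compared by Spearman's correlation over the condensed
vectors (the lower triangle excluding the diagonal), with missing
entries excluded pairwise; fewer than 3 valid pairs yields NaN, flagged.

## Surface searchlight

Searchlight disks collect the voxels of all mesh vertices strictly less
than a geodesic radius (default 9 mm) from each centre vertex, with
geodesic distance approximated by Dijkstra shortest paths along mesh
edges weighted by Euclidean length.  Voxels mapped from several
in-range vertices enter a disk once (nearest-first); vertices whose
disk contains no mapped voxel are dropped and logged.  Deduplication
happens after distance selection.  Each disk's voxel patterns feed the
correlation metric, giving a vertex-resolved RDM map.

The flat test lattice (`build_toy_mesh`) carries the standard
two-triangles-per-cell topology plus the second cell diagonal as an
explicit extra graph edge.  The reason is geometric: a planar
triangulation can hold only one diagonal per cell, and that arbitrary
orientation choice makes graph distances anisotropic — the mirrored
(2,2)-cell neighbour sits at 2+√2 spacings instead of 2√2, and no
assignment of orientations fixes every vertex (the demands of vertices
(r,c) and (r,c+3) conflict on the cell between them).  With both
diagonals the lattice graph is direction-unbiased, and disk membership
at radius 3× the spacing coincides exactly with the flat surface's
true geodesic (Euclidean) disks, which is what makes the fixture
verifiable.  Meshes loaded from surface files use face edges only.

## Latency and hierarchy statistics

Similarity time courses (one value per subject and timepoint) are
summarised by **peak latency** — the time of maximal similarity within
a window (default post-stimulus; ties resolve to the earliest point,
which is conservative for "later layers peak later" claims) — and
**onset latency**, defined here as the first timepoint of the earliest
significant cluster after stimulus onset (the literature leaves the
definition open; this choice ties onsets to the same inference used
everywhere else).

The **hierarchy statistic** relates model layer number to peak latency.
Per subject, Spearman's R between layer index and that subject's peak
latencies is computed (undefined latencies excluded pairwise; subjects
with fewer than two valid layers are dropped and logged).  Two group
summaries are reported: the mean of per-subject Rs (paired with the
sign-permutation p-value) and the Spearman R computed on
subject-averaged latencies, which is what a subject-average latency
plot displays.  The second is far less noisy because latency jitter
averages out before ranking; the first is the basis of inference.
Contrasts between models subtract per-subject Rs and test the mean
difference by sign permutation (two-sided by default — contrasts are
non-directional, similarities directional).

## Group inference

* **Sign-permutation test**: per-subject effects have exchangeable sign
  under the null; the group mean is recomputed under random sign
  flips (default 10,000 samples, identity included so p ≥ 1/n) with
  signs drawn per subject and applied jointly across all points,
  preserving within-subject correlation.  An exhaustive mode
  enumerates all `2^n` assignments (exact p) for n ≤ 20.
* **Cluster-extent correction**: per-point permutation p-values are
  thresholded (default p < 0.05); contiguous supra-threshold points
  (consecutive timepoints, or connected mesh components for surface
  maps) form clusters scored by extent with every point weighted
  equally.  The null is the maximal cluster extent per permutation,
  each permutation's point-wise p-values computed against the same
  permutation distribution; a cluster is significant when its extent
  exceeds the `1 − p/bonferroni` null quantile.  Two practical
  properties worth knowing: (i) integer extents make the test
  conservative on coarse grids (measured familywise error ≈1% at 61
  points versus ≈4–5% at ≥301 points with 15 subjects and 1,000
  permutations), so calibration analyses use millisecond-resolution
  grids; (ii) when the true effect is strong and temporally homogeneous
  over a short analysis window, the sign-flip draws that keep most
  signs positive reproduce the full supra-threshold span, the null
  max-extent saturates at the window length, and no cluster can clear a
  Bonferroni-tightened threshold — an inherent property of extent-based
  inference on windows without baseline, not an implementation
  artefact.
* **FDR**: Benjamini–Hochberg step-up, for families without adjacency
  structure.
* **Subject-pool bootstrap**: standard errors are the SD of the
  statistic over resamples of subjects with replacement (default
  1,000).  Paired-difference confidence intervals use the expanded
  percentile interval (percentiles at t-adjusted levels): the plain
  percentile interval of a mean undercovers at n = 15 (≈92.5% for a
  nominal 95%), and the expansion restores close-to-nominal coverage
  while remaining a percentile of the bootstrap distribution.
  `expand=False` gives the plain interval.

## Synthetic-data generator

The generator emulates the study design the pipeline targets: 118
image conditions, 15 subjects, 306 sensors, epochs from −100 to
+1000 ms at 1 ms, 30 trials per condition, 100-voxel region patterns,
and an 8-layer model.  Generation starts at the preprocessed-pattern
level; no sensor physics or hemodynamics are simulated.

**Shared latent geometry.** Each layer `l` owns a latent
condition-embedding matrix `Z_l` (conditions × d, default d = 20,
i.i.d. normal, drawn from a per-layer substream).  Its correlation RDM
is the layer's *target RDM*.  Observations in every space are linear
images of `Z_l` plus noise:

* model units and fMRI voxels use *feature tiling* (columns of `Z_l`
  repeated to the requested width, remainder columns drawn as a random
  subset).  Duplicating features transforms per-condition ranks
  affinely, so pairwise Spearman correlations — hence the correlation
  RDM — are preserved exactly: at zero noise the layer RDM equals its
  target up to remainder reweighting.  Random projections do not have
  this property (rank correlations are not rotation-invariant; measured
  agreement only ~0.86–0.92).
* MEG sensor patterns use a per-subject random orthonormal map, which
  preserves the pairwise Euclidean distances that drive linear
  decodability while giving every subject its own sensor topography.
  Sensor counts well above the total latent dimensionality
  (n_layers × d) matter here: in a crowded sensor space the layers'
  latent subspaces overlap, producing persistent subject-specific
  layer confusions.

**Temporal structure.** The noiseless sensor pattern at time t is
`Σ_l w_l(t)·B_l[c]`, with Gaussian kernels `w_l` centred at per-layer
latencies.  The kernel width parameter is the FWHM (default 20 ms,
matching the 20 ms smoothing-window scale of typical MEG
preprocessing; σ ≈ 8.5 ms).  Latencies default to `100 + 10·l` ms; a
hierarchy sign of −1 reverses the order, 0 collapses all layers onto
the mean latency.  Trials add i.i.d. Gaussian sensor noise, then a
20 ms box-car along time emulates sliding-window preprocessing; the
smoothed noise is rescaled so `noise_sd` remains the per-sample SD
regardless of the analysis grid — smoothing contributes only temporal
correlation.

**Noise levels.** Three knobs with different physical meaning:
`noise_sd` (per-trial, per-sensor recording noise; default 10, which
puts peak pairwise decoding at roughly 70–90%, the band published
sensor-level pairwise image-decoding curves peak in), `fmri_noise_sd`
(noise on voxel pattern estimates, which average many acquisitions;
default 1), and `model_noise_sd` (default 0 — model activations are
deterministic).  A single noise figure cannot serve all three spaces:
a realistic per-trial sensor noise is an order of magnitude above the
condition signal and would obliterate pattern-level structure if
applied to voxels or units.  The signal-to-noise ratio itself is a
free parameter of the generator (real recordings don't report one);
the default was calibrated once, by forward simulation against the
published decoding-accuracy range, and then frozen.

**fMRI regions** mix layer geometries with per-region weights in
[0, 1] summing to ≤ 1 (V1-like regions weight low layers, IT-like
regions high layers); a zero-weight region is pure noise.  **Noise
images** (for training-stimulus emulation) draw every pixel and
channel uniform [0, 1] and convolve with a 10 × 10 Gaussian kernel of
SD 80 px (nearly flat over its support) using reflective padding, so
border statistics match the interior; smoothing leaves the intended
faint spatial gradients (positive lag-1 autocorrelation).

All randomness flows from one experiment seed through named
`SeedSequence` substreams (stage, layer, subject), so any fixture is
bit-reproducible in isolation.

## Receptive-field mapping

For any extractor (a pure callable mapping an image batch to per-unit
activations), the K (default 25) most strongly activating images are
occluded by gray squares (default 8 px; dense grid or random
positions); the per-position activation drop is accumulated into a
per-pixel discrepancy map (each pixel averaging the occluders covering
it).  Maps are re-centred on their peaks (ties: first in scan order)
and averaged into the empirical receptive field.  A selectivity region
is the convolution of a feature map with the RF, thresholded at 50% of
its maximum.  Occluder size, stride/sample count, fill value and the
aggregation order are configurable because the underlying procedure is
only loosely standardised.

## Problem sizes used in validation

The validation suite and `scripts/acceptance.py` run the full pipeline
at documented desk scales chosen so that statistical recoveries retain
comfortable margins while a complete run stays in the minutes range:

* hierarchy recovery: 16 conditions, 15 subjects, 128 sensors, 30
  trials, k = 5, 8 sub-averaging repetitions, analysis grid
  60–240 ms at 10 ms, 64 units/layer (`RunConfig.desk_scale`).
  Measured: subject-mean-latency hierarchy R ≈ 0.98 (sign +1) and
  ≈ −0.96 (sign −1), 15/15 subjects with the injected sign,
  sign-permutation p ≈ 5 × 10⁻⁴.
* familywise-error calibration: 200 null experiments of 15 subjects ×
  301 timepoints, 1,000 permutations each.
* chance-level calibration: 50 two-condition datasets, 16 sensors,
  M = 30, k = 5, 100 repetitions.
* searchlight: 10 × 10 lattice at 3 mm, 9 mm disks, 16 conditions,
  6 subjects.

Generator *defaults* remain the emulated study's values (118
conditions, 306 sensors, 1 ms grid, 10,000 permutations, 1,000
bootstraps); the desk scales are explicit overrides.

## What passing tests do and do not show

The generator produces Gaussian, temporally smoothed, linearly mixed
signals with exchangeable trials and independent layer geometries.
Passing recovery tests therefore demonstrates that the pipeline's
statistics recover structure *of the kind the analysis assumes*, with
correct calibration under the matching null.  Real recordings violate
these assumptions in known ways — correlated sensor noise, non-Gaussian
artefacts, layer RDMs correlated across layers, subject-specific
latency spreads, imperfect trial counts — so green tests certify the
analysis machinery, not the neuroscientific conclusions one would draw
from applying it to data.  Channel-unit harmonisation for mixed sensor
types (gradiometers/magnetometers) is intentionally out of scope and
must be handled upstream of the `TrialTensor` contract.

## Known limitations

* Decoding at one timepoint fits `O(pairs × folds × reps)` small SVMs;
  full-scale 118-condition, 1101-timepoint runs are batch jobs, not
  interactive ones (the per-timepoint child-seed scheme makes them
  embarrassingly parallel; `--jobs` changes wall time, never results).
* Onset latencies inherit the cluster-saturation property above: on
  short homogeneous windows they may be undefined even for strong
  effects (logged as NaN).
* The volumetric searchlight, partial-correlation layer-unique
  analysis, and crossnobis/Euclidean RDM metrics are extension points,
  not implemented.
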