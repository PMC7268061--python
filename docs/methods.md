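# Methods

## Model and statistic

The unit of analysis is the contrast: one statistical comparison from one
study, carrying its reported peak coordinates (foci), sample size N and
analysis design (fixed or random effects). For each contrast a binary
contrast indicator map (CIM) marks every voxel whose center lies within
the kernel radius of any focus; the summary density at voxel v is

    P(v) = Σ_c w_c I_c(v) / Σ_c w_c,   w_c = √N_c · δ(design_c),

with δ = 0.75 for fixed-effects and 1.00 for random-effects contrasts.
P(v) ∈ [0, 1] is the weighted proportion of contrasts activating within
the kernel of v; it is the quantity reported per cluster as "Maxstat".
Replicating a contrast's peak list changes nothing (binary union within
the contrast), while splitting one contrast into two does — the
multilevel structure is the point of the method.

Assumptions: foci are comparable across studies once mapped to a common
space; within-contrast peak multiplicity is reporting noise, not signal;
the spatial uncertainty of a peak is captured by a hard 10 mm sphere.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| kernel radius | 10 | mm | conventional MKDA smoothing scale; closed ball (≤) on voxel-center distance |
| δ fixed / random | 0.75 / 1.00 | — | down-weights fixed-effects contrasts, which generalise less |
| voxel size | 2×2×2 | mm | standard MNI analysis grid |
| FWER p | 0.05 | — | family-wise error rate for height and extent criteria |
| primary alphas | .001, .01, .05 | — | uncorrected voxel cutoffs feeding the extent analysis |
| iterations | 5000 | — | production Monte-Carlo precision; tests and examples scale down |
| connectivity | 18 | — | SPM's cluster contiguity convention; 6 and 26 available |
| conjunction min cluster | 10 | voxels | discards conjoint specks |

## Numerical conventions

* **mm→voxel rounding** is half-away-from-zero (so (1,1,1) mm on a 2 mm
  grid maps to voxel (1,1,1)), applied when snapping foci to the lattice.
* **Sphere membership** uses ≤ on center-to-center mm distance (with a
  1e-9 slack on the squared distance so exact-boundary voxels are kept
  under floating point). Foci are snapped to their nearest voxel center
  before stamping, making CIM construction exact on the lattice; the
  brute-force oracle in the tests uses the same convention.
* **Mask clipping** happens after the union over foci, so an out-of-mask
  focus still marks nearby in-mask voxels.
* **Empirical thresholds** use the ceiling convention: the smallest
  observed value t with exceedance fraction ≤ p. When even the largest
  value is too frequent (ties), the threshold is placed just above it and
  nothing passes — conservative by construction. Cluster-extent
  thresholds are the smallest *integer* k with P(max cluster ≥ k) ≤ p,
  which may fall between observed sizes.
* **Null density histogram** is exact, not subsampled: weighted densities
  take finitely many values (subset sums of weights over Σw), pooled in a
  dictionary after rounding to 12 decimals to merge float-identical
  values.
* **Seeding**: one master seed per run; per-iteration generators are
  spawned from a `SeedSequence`, so results are bitwise reproducible and
  independent of iteration order. The Monte-Carlo null is computed in two
  passes over the same substreams: maxima and the pooled histogram first
  (defining the primary cutoffs), then a regeneration pass recording the
  largest suprathreshold cluster per alpha — chosen over caching all null
  maps to keep memory flat.
* The vectorised null engine stamps kernels by flat-index arithmetic on a
  padded grid and enforces the per-contrast binary union with one sort;
  the test suite asserts its output equals the naive per-voxel
  computation exactly.

## Design choices

* **Randomisation unit**: by default each focus is relocated
  independently to a uniform in-mask voxel center, preserving
  per-contrast focus counts — this matches the stated null of uniformly
  scattered peaks. A blob-wise variant
  (`randomize_unit="blob"`) instead groups a contrast's foci whose
  spheres overlap and translates each group rigidly, preserving
  within-contrast spatial structure, for comparability with toolboxes
  that randomise contiguous activation blobs.
* **Combined map** = union of the height criterion and the extent
  criterion at the configured primary alpha (default .05), matching how
  results tables list clusters per criterion; an intersection mode is
  available (`ThresholdSpec.combine`).
* **Subtraction null** permutes contrast-to-domain labels with group
  sizes preserved. Relocating foci cannot generate a null for a
  *between-domain* difference — under label exchange the difference map
  is exchangeable, which is exactly the hypothesis being tested. Upper
  and lower thresholds are taken at FWER p per tail from the permuted
  whole-brain max and min.
* **Talairach→MNI**: pluggable affine, defaulting to the inverse of the
  pooled Lancaster MNI→Talairach matrix; identity is available, and the
  choice is recorded in run manifests because reported cluster
  coordinates depend on it.
* **Provenance guard**: density maps and null distributions carry the
  kernel radius, weight deltas, contrast count, weight sum and a mask
  fingerprint; thresholding refuses mismatched pairs so thresholds are
  never applied across analyses.
* **Participants per study** in dataset summaries are counted once per
  study (max over its contrasts when they differ), so multi-contrast
  studies do not inflate totals.
* **Conjunction peak** is the scan-order-first voxel maximising the mean
  of the two domains' densities; each cluster reports both domains'
  maxima *and* their mean, since either may be wanted as the cluster
  statistic.

## Synthetic data

`synthetic_data` draws StudySets from a generative model with the nesting
structure the method assumes: studies contribute 1–3 contrasts; sample
sizes are discrete-uniform on 8–30 (the span typical of the underlying
literature); 15% of contrasts are fixed-effects; each planted convergence
center is activated per contrast with probability 0.8 and isotropic
Gaussian jitter of 4 mm sd (resampled until in-mask, at most 100 tries,
then snapped to the nearest in-mask voxel — keeping focus counts fixed,
which the randomisation test relies on); 2–8 uniform noise foci per
contrast. The default test mask is a procedural 40×48×40-voxel ellipsoid
at 2 mm ("toy brain", ~29k voxels), small enough for minutes-scale
Monte-Carlo.

What the generator does **not** emulate: publication bias, coordinate
rounding to whole millimetres, anatomically structured noise, correlated
contrasts within a study, or realistic gray-matter geometry. Passing
tests therefore demonstrate the correctness and calibration of the
inference chain under its own null and signal model, not robustness to
those real-data features.

## Problem sizes used in validation

Desk-scale runs keep the suite fast while preserving the statistical
content: the density oracle uses 50 random StudySets on a 24³ grid; FWER
calibration uses 200 independent null datasets of 20 contrasts, each
calibrated with its own 500-iteration null on the toy mask; conjunction
recovery uses 50 replicates of two 15-contrast domains at 150 iterations
with primary alpha .05. A production analysis would use a real
gray-matter mask and 5,000 iterations.

## Known limitations

* Only spherical indicator kernels (no Gaussian/ALE kernels) and no
  effect-size meta-analysis.
* No analytic FWER approximation and no voxelwise FDR — thresholds are
  Monte-Carlo only.
* Anatomical labelling of clusters is out of scope; tables carry
  coordinates only.
* Primary thresholds are always pooled across iterations (no
  per-iteration primary cutoffs).
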