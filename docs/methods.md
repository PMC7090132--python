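# Methods

## The problem

Single neurons imaged by confocal or 2-photon microscopy must be separated
from their background — and from neighbouring, densely packed cells — as
*volumes*, not just traced centerlines, so that morphometric quantities
(volume, surface, Sholl profile) remain available.  Global thresholds fail
on such stacks because both the background level and the fluorophore
density vary across the volume.  This package implements a smart
region-growing (SmRG) segmentation whose admission rule is re-estimated
locally from the pixel statistics of each crop, plus the downstream
skeletonization, morphometry and reconstruction-comparison machinery, and a
synthetic phantom generator that provides exact ground truth.

## The local intensity model

Photon-counting statistics of a crop are modelled as a two-component
mixture sharing an integer detector offset `K0`:

    psi(y) = alpha * psi_B(y - K0) + (1 - alpha) * psi_S(y - K0)

* `psi_B`: a **discrete normal** with variance `vB` — the background peak.
  Its normaliser `Z(vB)` is computed by explicit summation over the integer
  window `K0 ± 6*sqrt(vB)`.
* `psi_S`: a **negative binomial** on the excess counts `k = y - K0` with
  size `r` and success probability `p`, re-parameterised through its
  moments `p = muS/vS`, `r = muS^2/(vS - muS)`; zero for `y < K0`.
* `alpha`: prior background probability of a voxel.

Fitting is by EM on the crop histogram.  The E-step computes per-level
background responsibilities; the M-step sets `alpha` to the responsibility
mean, maximises the background-restricted log-likelihood over an integer
grid of `K0` (mode ± 10) with `vB` the responsibility-weighted mean squared
deviation, and updates `(p, r)` by responsibility-weighted method of
moments.  Two guards keep the procedure honest:

* **Monotonicity gate.**  Moment updates are not ascent steps, so each
  iteration is accepted only if the observed log-likelihood does not
  decrease (generalized EM with candidate fallbacks).  The reported
  `loglik_trace` is therefore non-decreasing by construction, and the test
  suite asserts it to 1e-8 per step.
* **BIC pruning.**  On pure-background crops the unconstrained mixture
  spends its signal component on the upper half of the normal peak.  At
  convergence the fit is compared against the best single discrete normal;
  if the likelihood gain is below `1.5 * ln(n)` the background-only model
  (`alpha = 1`) is reported.

Underdispersed transient moment estimates (`vS <= muS`) are clamped to
`p = 0.99`, `r = muS*p/(1-p)` instead of aborting the iteration.
Initialisation is deterministic (histogram mode, variance of the
sub-modal half, moments of the remainder), so fits are reproducible.
Convergence: relative log-likelihood change below 1e-6, at most 200
iterations.

## The growing loop

From each seed a crop of `max(edge/8, 32) x max(edge/8, 32) x 3` voxels is
extracted, shifted inward at stack borders (never padded, and never
shrunken while the stack allows it — this keeps the histogram sample size,
and with it the bootstrap table of the dip test, constant).  Per crop:

1. **Modality gate.**  Hartigan's dip test on the crop intensities decides
   between thresholding methods at p < 0.01: multimodal crops (structure
   and background both prominent) go to **Otsu's threshold** computed on
   the exact integer histogram with a strictly-greater-than foreground
   rule; unimodal crops get the **EM mixture** and admit voxels whose
   signal posterior exceeds `tau = 0.999`.
2. **Connectivity.**  Only admitted voxels 26-connected to the seed within
   the crop are kept (thin oblique neurites break under 6-connectivity).
3. **Reseeding.**  New seeds are derived from the per-plane Euclidean
   distance transform of the newly segmented crop (below).
4. Results are OR-ed into the global mask; no voxel is ever removed, so
   the mask grows monotonically and the loop terminates (each candidate
   position is processed at most once; FIFO order keeps crops near
   already-fitted statistics).

**Dip test details.**  The dip statistic (minimal sup-distance between the
ECDF and the closest unimodal CDF) is computed with the modal-interval
GCM/LCM iteration and validated in the test suite against an independent
linear-programming oracle.  p-values follow the original recipe — a
bootstrap of B = 2000 uniform samples of the observed size, seeded and
cached per size.  Integer-quantised samples are first dithered with a
seeded uniform box of one quantisation step: the dip of heavily tied data
is inflated several-fold relative to the continuous null, which would
otherwise route *every* quantised crop to Otsu; dithering preserves the
modality of the underlying histogram.  Samples smaller than 8 are called
unimodal by convention.

**Reseeding details.**  The published description — "regional maxima of the
distance transform" — has a degenerate limit on noiseless data: the EDT
ridge of a cleanly rasterised straight tube is *exactly* constant, and
wherever it touches a thicker region (a junction, a soma) it has a greater
neighbour and contains no regional maximum at all; a plateau-centroid rule
additionally collapses any window-cut tube to a mid-crop fixed point.  Real
microscopy masks have ragged boundaries that fragment the ridge into many
maxima, which is why the published rule works in practice.  This
implementation makes the intent explicit: per plane it extracts the ridge
of the distance transform (2-D thinning on an edge-padded plane, united
with the genuine regional maxima) and emits, per connected ridge component,
(i) the voxel nearest the component centroid, (ii) the two component
extremities when the component is elongated relative to its thickness
(spread > 3x max EDT — a tube running along the plane), and (iii) one
continuation point per crop edge the component touches.  Compact blobs
(somata, perpendicular tube cross-sections) still yield a single central
seed; elongated structures always reseed the growth front to the crop
boundary.

**Seed bookkeeping.**  Taken literally, "skip a popped seed already in the
global mask" would end the procedure after one crop, because every reseeded
position lies inside the region just segmented.  Seeds are instead
deduplicated against the set of positions ever enqueued, and each position
is processed once.

**Automatic seeding.**  Somata are found by a 3-D spherical Hough
transform: Otsu-binarised boundary voxels vote via FFT correlation with
spherical shells over the requested radius range; accumulator peaks above a
coverage fraction of 0.33 become seeds with non-maximum suppression at
twice the detected radius.

## Skeleton and SWC

Masks are thinned with the Lee medial-surface-axis algorithm (3-D
`skimage.morphology.skeletonize`), preserving 26-connectivity component
counts.  The skeleton becomes an SWC tree by breadth-first spanning tree
over 26-adjacent skeleton voxels, rooted at the voxel nearest the seed
(cycles from thinning artifacts are broken by BFS order); one node per
skeleton voxel, no resampling.  Node radius is the mask's Euclidean
distance transform at the voxel scaled by the mean on-plane voxel size
(the thickness estimator is not otherwise specified in the literature this
follows); coordinates are exported in µm, root/soma node type 1, all
others 3.

## Morphometry

* **Volume**: voxel count x voxel volume.
* **Surface area**: exposed voxel faces (exact for the voxel solid) or
  marching-cubes iso-surface area (closer to the true area of round
  objects; on a rasterised r=10 sphere it is ~9% above `4*pi*r^2`, the
  voxelisation limit of a binary iso-surface).
* **Sholl profile**: for radius `k*step` the number of 26-connected
  components of mask voxels inside the spherical shell of half-width
  `h = half a voxel diagonal` (the smallest h that guarantees every
  crossing neurite intersects the shell); this counts *crossings*, not
  voxels.  The profile's AUC uses the trapezoidal rule.  The Sholl centre
  defaults to the structure centroid (a property of the output, not of the
  seed) and is overridable.

## Comparison metrics

For node sets A (test) and B (reference), with `d_AB(i)` the distance from
node i of A to its nearest node of B:

* `SD = sum d_AB/(2|A|) + sum d_BA/(2|B|)`.
* `SSD` restricts both directions to distances above a tolerance S
  (default 2 voxels) and averages the two directed means (each over its own
  surviving set; an empty set contributes 0, and with no contributors at
  all SSD = SSD% = 0 — "no substantial discrepancy").  `SSD%` is the
  percentage of contributing nodes.
* **Precision/recall/F.**  Default matching is *nearest-correspondence
  coverage*: precision is the fraction of test nodes with a reference node
  within S, recall the converse.  A greedy one-to-one matching (ascending
  pair distance) is also provided, but it structurally caps F at ~0.83 for
  geometrically perfect reconstructions whenever the node densities differ
  (a one-node-per-voxel skeleton samples diagonal runs every sqrt(2)
  voxels; a 1 µm-arc-length ground truth every 1.0) — the coverage reading
  is the one consistent with reported F-scores above 0.95 and is used by
  default.  Both are exhaustively oracle-tested; all metrics are monotone
  in S.

Units are whatever the input SWCs are in (voxels for phantom work, µm for
real stacks).

## Phantoms

A phantom is a tree of linearly tapered capsules plus an optional spherical
soma, rasterised by a voxel-centre-in-solid test, with the ground-truth
centerline sampled at one-voxel arc length.  Rendering draws background
voxels from `K0 + round(N(0, vB))` clipped at zero and structure voxels
from `K0 + NB(r, p)`, i.i.d. given the mask — exactly the segmentation
model, deliberately: the base suite tests the method under its own
assumptions, and an optional Gaussian PSF blur is the stress knob left to
the user.  What a green phantom test does *not* establish: robustness to
partial-volume mixing at neurite boundaries, depth-dependent attenuation,
or correlated noise.

The standard suite fixes four named phantoms (straight tube, Y-branch,
Purkinje-like tree with soma, two touching somata) at three contrast tiers
with `K0 = 100`, `vB = 25` and `muS/sigma_B` of 10 (high, muS = 50), 5
(medium) and 2.5 (low); signal variance is `2*muS` (p = 0.5).  Seeds are
fixed per phantom/tier.  At the low tier the `tau = 0.999` predicate admits
almost nothing — segmentation from a tube seed typically returns an empty
mask.  That degradation is expected and documented rather than patched: at
2.5 background standard deviations of contrast the model itself assigns no
voxel a 99.9% signal posterior.

## Numerical and degenerate-input choices

* Crop histograms with a single intensity level: EM returns a flagged
  non-converged background-only report; Otsu raises on constant input and
  the crop admits nothing.
* EM non-convergence inside the growing loop falls back to Otsu with a
  logged warning.
* Pixels below `K0` have zero signal density (factorial domain of the
  negative binomial).
* The dip bootstrap table is seeded (`20200317 + n`), so p-values, and
  with them every segmentation, are bit-reproducible.
* Ties in hull construction resolve to the farthest point (collinear
  interior points are not hull vertices); the modal-interval argmax
  tie-breaks to the smallest index so the interval always shrinks.

## Reproducibility harness

`smrg reproducibility` (library: `smrg.cli.reproducibility_cvs`) re-grows
the same stack from each given seed and reports the coefficient of
variation of volume, voxel-face surface area and Sholl AUC.  Background
seeds (empty segmentations) are excluded with a warning.  On the
high-contrast Y-branch phantom all 10-seed CVs are 0 to machine precision
(every seed converges to the identical mask); the acceptance threshold is
CV < 0.05.

Statistical comparison of morphometric features across segmenters (the
Friedman test with replicates used in accuracy studies) is a standard
library call and intentionally not re-implemented; e.g.:

```python
from scipy.stats import friedmanchisquare
friedmanchisquare(volumes_by_rater_1, volumes_by_rater_2, volumes_by_smrg)
```

## Known limitations

* The watershed post-splitting of touching neurons is out of scope; the
  two-somata phantom documents the failure mode (one merged component).
* Growth and connectivity operate in voxel space; strong anisotropy is
  only accounted for in morphometry and SWC export.
* The spherical Hough seeding assumes roughly isotropic voxels and
  spherical somata.
* Single-channel, integer-intensity stacks only.
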