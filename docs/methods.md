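# Methods

## Problem and model

Guided implant surgery transfers a CT-based plan to the patient through a
chain of physical models: an impression, a gypsum cast, an acrylic-resin
radiographic template worn during the CT, and a stereolithographic surgical
guide.  Each hand-off loses accuracy.  The verification strategy implemented
here uses an optical structured-light scan — roughly an order of magnitude
more accurate than CT — as the gold standard: every CT-derived or
manufactured surface is rigidly aligned to its optical counterpart and the
distribution of signed point-to-surface distances is examined.

The dominant tunable error source in the CT branch is the segmentation
threshold τ.  A CT volume blurred by the scanner point-spread function turns
the sharp object boundary into a smooth intensity ramp; the marching-cubes
isosurface at isovalue τ therefore moves continuously with τ: low thresholds
reconstruct the object too large, high thresholds too small.  The calibrated
threshold τ\* is the one minimizing the absolute mean signed deviation
against the optical surface.

## Pipeline

1. **Segmentation** — superlevel-set mask (`intensity ≥ τ`, the ≥ convention
   is fixed so voxel counts are exactly reproducible), optional largest
   26-connected component, marching cubes (topology-consistent Lewiner case
   table) with linearly interpolated vertices mapped through the single
   shared voxel→world convention `world = origin + index · spacing`.
   No smoothing or decimation: deviations must measure segmentation error,
   not post-processing.
2. **Registration** — closed-form Kabsch/Arun SVD fit of user-picked
   landmark pairs (reflection corrected so det(R) = +1), refined by trimmed
   point-to-point ICP.  Correspondences are exact point-to-triangle
   projections found by a certified KD-tree search (see below); the worst
   10 % of correspondences is discarded each iteration (default
   `trim_fraction = 0.1`), which makes partial overlap harmless and keeps
   each update deterministic.  Point-to-point (not point-to-plane) error was
   chosen for robustness on noisy phantom normals.
3. **Deviation** — exact signed distances from seeded samples of the test
   surface to the gold surface.  The magnitude is the Euclidean distance to
   the nearest point on any triangle; the sign comes from the angle-weighted
   pseudo-normal of the closest feature (face / edge / vertex), with a
   generalized-winding-number signer available for watertight meshes.
   Positive mean ⇒ test model larger than gold.  Statistics use the
   population (1/n) standard deviation — with 10⁴–10⁶ samples the
   distinction from 1/(n−1) is negligible, but the convention is fixed and
   recorded in every report.  Histograms are anchored at 0 with a default
   bin width of 0.05 mm so over- and under-sized regions read symmetrically.
4. **Threshold search** — the mean deviation is monotone decreasing in τ, so
   the search is a 9-point coarse grid over the bracket followed by
   bisection on the *sign* of the mean, terminating when |mean| < 0.005 mm
   or the bracket is narrower than the intensity resolution (1 CT unit).
   Bisection on the sign is robust where |mean| has a flat noise floor;
   golden-section on |mean| is not.  Registration is computed once, at the
   median grid threshold, and reused for nearby τ — re-running ICP per
   candidate would couple registration noise into the objective
   (re-registration per τ is available via a flag).

## Closest-point engine

`rtree`-style spatial indexing is not assumed; instead queries are certified
with a KD-tree over triangle centroids: after evaluating the k nearest
candidate triangles exactly, the result is provably optimal once the best
exact distance is ≤ (distance to the k-th centroid) − r_max, where r_max
bounds any triangle's centroid-to-surface radius; otherwise k escalates
until the whole mesh is scanned.  Oversized triangles are bisected at build
time (a pure query-side refinement that leaves the surface unchanged) to
keep r_max tight.  The engine is validated against an exhaustive
all-triangles reference that shares no geometry code (candidate plane/edge
projections, winding-number sign); the two agree to < 1e-12 mm on random
watertight meshes.

## Surface sampling

Area-weighted sampling picks a face with probability proportional to its
area and returns **one of its corners** (a mesh vertex) rather than an
interior barycentric point.  Rationale: the optical noise model lives on
mesh vertices (each measured point is displaced along its normal by iid
N(0, σ²)); an interior point interpolates three iid offsets and attenuates
the noise SD by ≈ 1/√2, so interior sampling would systematically
under-report scanner noise in RMS and SD readouts.  Vertex-corner sampling
preserves the per-point error statistics; classic interior sampling is
available with `interior=True` and is equivalent for noise-free surfaces.

## Phantom generator

Patient CT and optical scans behind this kind of workflow are not publicly
available, so the package ships a synthetic stand-in with known ground
truth: a horseshoe-shaped swept tube (circular-arc centreline, circular
cross-section with sinusoidal "tooth-cusp" radius modulation) voxelized at
CT-like spacing, blurred with a Gaussian PSF, and separately posed/noised as
an optical scan.

Defaults and why:

| parameter | default | rationale |
|---|---|---|
| arch_radius | 22 mm | dental-arch scale (≈ 44 mm wide) |
| tube_radius | 8 mm | denture-base ridge cross-section (≈ 16 mm); also keeps the PSF curvature bias small (see below) |
| arc_span | 120° | horseshoe segment at desk scale |
| bump_count / amplitude | 5 / 0.8 mm | cusp-scale surface relief; periodic modulation averages to zero curvature, so it widens the deviation SD without biasing the mean |
| fg / bg intensity | 1000 / 0 | CT-like contrast for acrylic resin; mid level 500 is the ideal isovalue |
| psf_sigma | 0.6 mm | partial-volume blur of a standard reconstruction kernel |
| optical_noise_sd | 0.01 mm | accuracy class of structured-light dental scanners |
| spacing (study) | 0.3–0.5 mm | 0.5 mm slice thickness is typical of maxillofacial CT; 0.3 mm used for the threshold-recovery experiment |

A physics constraint informed the tube radius: Gaussian blur moves the
half-level set of an indicator inward by ≈ σ²·H (H = mean curvature), so the
zero-mean threshold sits slightly *below* the mid intensity on convex
objects.  With σ = 0.6 mm and r = 8 mm the bias is ≈ 0.02 mm (≈ 15–20 CT
units of threshold shift), small against the 1000-unit contrast.  The
measured τ\* ≈ 481 on the default phantom matches this estimate.  For a
torus-like tube the second principal curvature integrates to zero over the
surface, so only 1/(2r) contributes to the mean.

What the phantom does **not** emulate: beam hardening, metal artifacts,
anatomical shape, scanner calibration drift, occlusion/line-of-sight gaps in
optical scans.  Passing tests therefore demonstrate the correctness and
calibration of the *algorithms* (registration, signed distances, threshold
search) under controlled conditions, not clinical accuracy on real scans.

## Numerical choices and degenerate inputs

* Inside/outside tests during voxelization use voxel centres; voxels far
  from the surface are settled block-wise (connected blocks outside a
  guaranteed distance band of the surface are uniformly inside or outside;
  one representative signed-distance query per block), which keeps exact
  voxelization of ~10⁶-voxel grids to seconds.
* Volume grids are strictly axis-aligned; oblique DICOM orientations are
  rejected rather than silently misread.  The slice axis is the third index.
* STL vertex merging tolerance is 1e-6 mm (STL duplicates vertices per
  facet); degenerate and duplicate faces are dropped with a recorded count.
* Rigid transforms are validated to orthonormality/det = +1 at 1e-8;
  rotation magnitudes are computed with atan2 of the skew norm, which stays
  accurate near the identity where arccos of the trace loses half the
  digits.
* Component ties in `largest_component` break to the component containing
  the lowest linear voxel index; thresholding uses ≥.
* ICP reports RMS over all correspondences (trimming affects only the
  update) and sets a `converged` flag instead of raising when the iteration
  cap is hit.  Lattice-commensurate voxel grids (grid planes exactly through
  a mesh's extremal planes) are a degenerate alignment for volume
  measurement; tests use generic offsets.

## Problem sizes

Test and study runs use desk-scale sizes chosen to keep the full suite
interactive: arch phantoms of ~25 k vertices, CT grids of 0.5–1.6 M voxels
(0.3–0.6 mm spacing), 3–20 k deviation samples, 1.5–5 k ICP samples.  All
random stages (sampling, noise, perturbations) are seeded; identical seeds
reproduce every report byte-for-byte except timestamps.

## Known limitations

* Mean-curvature bias: τ\* compensates the σ²·H shift *on average*; locally
  the isosurface is still displaced where curvature deviates from the mean,
  which is visible as deviation SD, not mean.
* The monotone-mean assumption underlying sign bisection can break on
  multi-material volumes; the grid stage falls back to the |mean| minimum
  with a warning when no sign change is bracketed.
* Point-to-point ICP converges slowly along sliding directions of
  near-symmetric shapes; the arch's end caps and cusps bound this, but
  highly symmetric inputs (a full torus) would register with a free
  parameter.
* ROI geodesics are graph distances along mesh edges, an upper bound on true
  geodesic distance; adequate for seed-plus-radius mating-surface selection,
  not for exact geodesic analysis.
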