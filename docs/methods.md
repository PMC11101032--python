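# Methods

## Scope and coordinate conventions

The package builds voxelized breast models for microwave imaging from four
co-registered MRI-like channels: Dixon in-phase (I), fat-only (F),
water-only (W) and a contrast-enhanced subtraction volume.  Inputs are
assumed co-registered; registration is out of scope.  Arrays are stored
`(z, y, x)` with `y` increasing anterior → posterior (prone geometry: the
breasts hang at low `y`, the chest wall sits at high `y`); on disk, volumes
are MetaImage (MHA) files whose `DimSize` is `(x, y, z)` per the standard.
Physical position is `origin + index·spacing` with the voxel-center
convention, matching ITK.

## Pre-processing

Each channel passes through, in this fixed order:

1. **Bias-field correction.**  The contract is estimator-agnostic: the
   image is divided by a smooth strictly positive field normalized to unit
   geometric mean over the foreground (the top 90% of positive
   intensities), and the output is rescaled to preserve the foreground
   mean.  The default estimator is SimpleITK's N4 (B-spline field fitted on
   a ~32-voxel-per-axis shrunken copy, 3 levels × 25 iterations); N4's
   histogram-sharpening objective keeps tissue contrast out of the field.
   A self-contained order-3 log-domain polynomial estimator is provided as
   an alternative (`bias_method="polynomial"`); it is exact on
   homogeneous-foreground volumes but, like any unregularized trend fit,
   absorbs anatomy-scale intensity structure on multi-tissue volumes, which
   is why it is not the default.
2. **Min-max normalization** to [0, 1]; constant volumes map to zeros with
   a warning.
3. **Median filtering** over the cubic (2r+1)³ neighborhood with
   edge replication, default radius 1 (3×3×3) — the smallest kernel, chosen
   to preserve fine structure.  For exams containing an infra-centimetric
   tumor (< 1 cm) the median step is skipped on *all* channels, since a
   3×3×3 median visibly erodes lesions a few voxels across.  The flag is an
   explicit input: detecting lesion size would require the segmentation
   this step precedes.

## Anatomy segmentation

* **Sternum seed.**  The mid-sagittal column of the central axial slice is
  scanned anterior → posterior; the first voxel starting a run of ≥ 3
  voxels with W > 0.5 marks the water-rich chest-wall muscle.  The scan is
  deliberately confined to the midline so lateral asymmetry cannot attract
  the seed.
* **Breast-fat growing.**  Running-mean region growing (6-connectivity,
  default tolerance 0.15 normalized units) on the F channel.  Growth is
  wave-synchronous: each wave accepts candidates within the tolerance of
  the current region mean, so the result is independent of traversal order
  within a wave, and voxels rejected early may be reconsidered if the mean
  drifts.  The chest-wall muscle is F-dark, so growth halts there and
  thoracic fat is excluded.  One seed is derived per lateral half (the
  brightest F voxel anterior of the chest wall in the central slice),
  because the two breasts need not be fat-connected across the midline.
* **Breast region.**  The fat mask is dilated with a Euclidean ball of
  radius 3 (implemented exactly via the distance transform), then each
  (z, x) column of the body envelope is filled anterior to the
  posterior-most dilated-fat voxel, capturing skin and enclosed
  fibroglandular tissue.  The body envelope is the largest hole-filled
  component of I > 0.15.
* **Posterior trim.**  The column fill is bounded by the *dilated* fat
  mask, so its last ~3 layers carry no fat evidence; anatomically the
  tissue behind the posterior-most fat (behind the retromammary fat) is
  chest wall.  Breast-region voxels posterior of the undilated fat in
  their column are therefore reassigned to the muscle compartment before
  classification.  Without this trim, roughly three chest-wall layers per
  column would enter the fibroglandular/fat mixture.
* **Skin and muscle shells.**  Skin = breast-region voxels within the skin
  thickness (default 2 voxels ≈ 2 mm) of non-body space; muscle = the
  posterior shell of the breast region inside the body, default thickness
  15 voxels (≈ 1.5 cm, a realistic pectoral thickness; a thin shell would
  barely overlap the pectoral slab given the 3-layer dilation intrusion
  described above).  The two masks are disjoint by construction.
* **Tissue classification.**  A two-component univariate Gaussian mixture
  (EM, tolerance 1e-6, ≤ 500 iterations, k-means++ initialization from a
  fixed recorded seed) is fitted per exam to interior I intensities; the
  brighter component is fat (fat is T1-bright in-phase).  Voxels whose
  maximum posterior falls below 0.9 become the transition class (label 4);
  each remaining class is split into intensity tertiles (balanced,
  reproducible subclasses).  Fewer than 100 interior voxels is an error.

## Tumor segmentation

Seeds are supplied as annotations (the benign/malignant kind is clinical
input, e.g. from radiological scoring — it is never computed) or
auto-proposed as the brightest voxel of each enhancing blob (subtraction
> 0.6 inside the breast region).  Regions grow under the same running-mean
rule, clipped to the breast region; the union is labeled by a single-pass
Hoshen–Kopelman union-find with 6-connectivity (the conservative standard),
ids relabeled 1..K by descending voxel count.  Clusters under 5 voxels are
discarded as noise (below the ~0.5 cm smallest lesion size the models
represent).  Each cluster yields a record with voxel count, equivalent
diameter `(6·V/π)^(1/3)` in cm, physical centroid and laterality; among
same-kind tumors of one exam, size classes XS < S < M < L < XL are assigned
by ascending volume (a lone tumor of a kind gets none).  Tumor labels
overwrite anatomy labels (benign −4, malignant −3).

## Dielectric assignment

Valid frequencies are 3.00, 3.01, …, 10.00 GHz (701 values); anything else
is rejected with the nearest valid values named.  Per voxel at frequency f:

* background → free space (εr = 1, σ = 0);
* skin and muscle → linear map between ±5% bound curves around the nominal
  Debye curve, anchored at the per-exam, per-class W-intensity extremes
  (the ±5% band is applied to both permittivity and conductivity);
* fat/fibroglandular subclasses → linear map between the adjacent subclass
  curves (clamped at the class extremes: e.g. fat_low spans
  [fat_low, fat_median], fat_median spans [fat_low, fat_high]); the
  transition class spans [fat_high, fibroglandular_low];
* benign tumors → linear map across the full fibroglandular envelope
  [fibroglandular_low, fibroglandular_high], since benign tumors and
  low-adipose breast tissue have similar dielectric properties;
* malignant tumors → the nominal Cole-Cole curve converted to a
  band-limited Debye equivalent, with no intensity spread by default.

Within every class the map is non-decreasing in W intensity, encoding
"brighter W = more water = higher εr and σeff".  A class at a single
intensity receives the envelope midpoint (the nominal curve).  Property
maps are float64 (downstream FDTD solvers are precision-sensitive; the
cost is negligible at these volume sizes).

**Parameter table provenance.**  The shipped CSV uses the literature
convention of a fixed 13 ps relaxation time for normal breast tissues in
this band: skin (ε∞ 15.93, Δε 23.83, σs 0.831) and muscle (21.66, 33.24,
0.886); three adipose rows spanning the low/median/high water-content
tertiles of ex-vivo measurements and three fibroglandular rows likewise;
the transition row is the midpoint of fat_high and fibroglandular_low.
The malignant row is the widely used 1-pole Cole-Cole fit to ex-vivo
malignant-tissue measurements (ε∞ 6.749, Δε 50.09, τ 10.5 ps, σs 0.794,
α 0.051).  The table is data, not code: editing the CSV (or passing
`--table`) changes every downstream map.

**Cole-Cole → Debye conversion.**  Least squares over the full 701-point
grid on the concatenated relative errors of εr and σeff, initialized at
the Cole-Cole values.  τ is carried in picoseconds inside the optimizer so
all four parameters share a comparable scale — with τ in seconds the
finite-difference Jacobian column vanishes in double precision.  An α = 0
input is a fixed point (recovered to ≤ 1e-6 relative); the α ≈ 0.05
malignant curve converts with < 5% band error.

## Synthetic phantom

The generator stands in for patient exams and defines the study
conditions.  Default geometry: a 64×128×128 grid at 0.9965 × 0.9965 × 1 mm
(the repository voxel size); two half-ellipsoid breasts (semi-axes
26 × 80 × 26 mm) hanging anterior of an 18-voxel pectoral slab, skin
shell 2 mm thick (the set of breast voxels within 2 mm of air), a
fibroglandular core occupying 25% of the breast interior carved from a
σ = 4 voxel low-pass Gaussian random field, separated from skin by 3 mm of
subcutaneous fat and from muscle by a 4 mm retromammary fat space (as in
real anatomy); thoracic tissue and fat pockets behind the chest wall; a
2-voxel chest skin layer.  Fibroglandular and fat subclasses are the
tertiles of their smooth fields, with W intensity increasing with
subclass water content.  Tumors are spheres with Gaussian-perturbed radius
fields (irregularity scales the perturbation), constrained to [0.5, 8] cm
diameter and to lie inside the breast interior; the default scenario is
one 2 cm malignant plus one 1.2 cm benign tumor in the left breast with a
healthy right breast, and presets cover tumor-free, single-tumor and
bilateral variants.

Channel intensities are per-tissue means (fat bright on F; water-rich
tissues bright on W and I; tumors bright only on subtraction), modulated
by a smooth multiplicative bias field (default amplitude 20%, σ = 24
voxels) and additive Gaussian noise (default σ = 0.05, a realistic SNR for
these sequences).  All randomness flows from one integer seed through
named `SeedSequence` spawns, so outputs are bitwise reproducible.

**What the phantom does not emulate:** MR physics (no sequence simulation
or k-space), partial-volume mixing at tissue interfaces, motion and ghosting
artifacts, inter-exam intensity variation, and anatomical variability of
real glandular trees (the smooth-field gland is blobbier than real
fibroglandular branching).  Passing recovery tests on phantoms therefore
demonstrates internal consistency of the chain under controlled
conditions, not clinical-grade accuracy on patient data.

## Numerical choices and degenerate inputs

* Tertile boundaries use linear-interpolation quantiles; exact ties at a
  boundary go to the lower subclass.
* Region growing accepts a candidate when |v − mean| ≤ tol with the mean
  updated between waves; seeds on background (≤ 0.05) are errors.
* `dilate_mask` thresholds the exact Euclidean distance transform, which
  equals ball dilation and stays fast at radius 15.
* Constant volumes: bias correction and normalization warn and return a
  no-op / zeros rather than raising.
* A degenerate intensity range in the dielectric map (single-intensity
  class) yields the envelope midpoint; out-of-range intensities are
  clamped with a warning.
* MHA headers are pre-validated before SimpleITK parses the file so that
  malformed files raise errors naming the offending key; `NDims ≠ 3` is a
  dimensionality error.

## Problem sizes

The recovery suite and the acceptance script run the full chain on the
default 64×128×128 grid (≈ 1.05 M voxels), once noiseless and once at 5%
noise / 20% bias — a size at which every stage, including N4 and the
mixture fit, completes in seconds while leaving tumors tens of voxels
across.  Labeling equivalence is checked on 200 random 32³ masks at 30%
occupancy; the dispersion oracle on 1000 random parameter sets.

## Known limitations

* Benign-tumor mapping uses the full fibroglandular envelope; whether the
  high-water end alone would be more faithful is an open modeling choice.
* The ±5% skin/muscle band is applied to conductivity as well as
  permittivity; applying it to permittivity only is a one-line table edit.
* The GMM is fitted per exam, not pooled across exams.
* Size classes are relative within an exam (per the XS–XL convention), so
  they are not comparable across exams.
* The sternum-seed rule assumes a water-bright chest wall on the midline;
  exams with midline implants or unusual anatomy would need a manual seed.
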