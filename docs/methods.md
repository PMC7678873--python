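# Methods

## Scope and coordinate conventions

All volumes are 3D scalar grids with isotropic voxel size carried in µm;
axis 0 is the LV long axis (base → apex), axes 1–2 span the short-axis
plane. Coordinates are 0-based voxel indices; physical units (mm³, ml, g)
appear only at reporting time. Vector fields store components in array-axis
order `(long, row, col)`; handedness is internal and consistent between the
phantom generator and the analysis, so helical-angle signs are meaningful
relative to each other (endocardial-positive by construction).

## Structure-tensor orientation analysis

Gradients are central differences (`numpy.gradient`; one-sided at the grid
boundary). The structure tensor is the Gaussian-windowed outer product
J = G_σ ∗ (g gᵀ), smoothed componentwise. The acquisition literature's
occasional phrase "cross product of gradient vectors" is read as this
standard outer-product construction: a literal cross product of a vector
with itself vanishes.

- `window_sigma` (default **2 voxels**): the accumulation window. The
  source workflows do not state their window, so this is a documented
  choice. Small windows preserve transmural HA resolution (the helix
  changes ~2.5°/voxel across a 40-voxel wall at full scale); large windows
  average more texture elements and tighten per-voxel v₃ estimates. With
  the default streak texture the per-voxel v₃ wobble is ≈7° (median) at
  σ = 2 and drops below 5°/95% at σ = 6; binned HA means are unbiased to
  within a few degrees in either case.
- `energy_eps` (default **1e-4**): voxels whose tensor trace falls below
  `energy_eps` × the 99th-percentile trace over the mask are invalid —
  this drops flat background leaking through imperfect masks. A constant
  volume has zero robust-max trace and is entirely invalid.

Eigenvalues are sorted descending and clipped at 0; v₃ is the eigenvector
of λ₃. Eigen-ties are resolved by LAPACK's deterministic ordering; the sign
of v₃ is meaningless until the helical-angle sign fix.

## Helical angle

HA = atan2(v₃·ẑ, v₃·ĉ) in degrees, after sign-fixing v₃ so its
circumferential component is ≥ 0 (when |v₃·ĉ| < 10⁻³ the longitudinal
component is made ≥ 0 instead, so an exact ±90° tie reports +90°). This is
the standard cardiac convention — the inclination of the fiber projected on
the local tangent plane. It coincides with the plane-elevation reading
arcsin(v₃·ẑ) whenever v₃ has no transmural component, which holds for
well-recovered fibers; with transmural wobble the atan2 form slightly
inflates |HA| (≈2–3° near mid-range angles at default settings).

The local frame is built per slice: transmural t̂ points from the slice LV
center to the voxel, ẑ is the long axis, ĉ = ẑ × t̂. The slice center is
the centroid of the enclosed cavity when one exists (full rings) and
otherwise a RANSAC circle fit to the outer boundary (partial rings: the
epicardial arc forms the consensus set, the straight cut edges are
outliers; observed center error ≈ 0.1 voxel on half-ring phantoms).

## Fractional anisotropy

FA = √(3/2)·‖λ − λ̄‖/‖λ‖, computed in the algebraically identical pairwise
difference form √[((λ₁−λ₂)² + (λ₂−λ₃)² + (λ₃−λ₁)²) / (2(λ₁²+λ₂²+λ₃²))] so
that equal triples give exactly 0 in floating point. FA of the all-zero
tensor is defined as 0. Results are clipped to [0, 1].

## Myocardial disarray index

Per voxel, the mean dyadic tensor D = ⟨v₃v₃ᵀ⟩ over the valid voxels of a
15×15×15 neighborhood (window positions outside the grid count as invalid;
voxels with < 10% valid neighbors carry no value), and
MDI = (3·λ_max(D) − 1)/2 clamped to [0, 1]. This is the nematic order
parameter of the orientation field: it is sign-invariant (orientations, not
directions), equals 1 for perfect collinearity, and 0 in expectation for
isotropic random vectors. The defining collinearity statistic is not
restated by the imaging literature this mirrors; the nematic order
parameter is adopted because it matches all stated MDI properties, and the
choice is documented here as an interpretation. Implementation:
box-filtered dyad components normalised by the box-filtered validity
fraction, then a 3×3 eigenvalue problem per voxel.

## Regional analysis

- **Segments**: 5 contiguous angular sectors (septal, posterior-septal,
  posterior, posterior-lateral, lateral) about the slice center. The
  anatomical angular extents are not standardised, so the default divides
  the mask's occupied angular span into five equal sectors (36° on a
  half-ring, 72° on a full ring); explicit boundaries are accepted and an
  error is raised if they fail to cover the mask.
- **Wall depth**: d_endo/(d_endo + d_epi) from per-slice Euclidean distance
  transforms to the endocardial and epicardial boundary sets — robust to
  non-circular, variably thick HCM-like walls, unlike a radial coordinate.
  Full rings identify the two boundaries by connectivity (the cavity does
  not touch the image border); partial rings split the complement radially
  about the estimated center, restricted to the mask's angular span so the
  cut faces do not act as wall boundary (depth is still distorted within
  roughly a wall thickness of the cut).
- **Transmural profiles**: mean/SD of HA in 10 equal depth bins; slope B1
  and R² from ordinary least squares on the binned means (empty bins are
  carried as missing and excluded; a constant profile reports B1 = 0 and
  R² = 0). The prescribed +50° → −50° phantom yields B1 ≈ −100°/unit depth
  with R² > 0.99.
- **Histograms** are density-normalised with shared bin edges, so the
  whole-section histogram equals the voxel-weighted combination of segment
  histograms exactly.

## Fibrosis volumetry

Seeded region growing on gray values: a voxel joins the region if it is
26-connected to it, lies in the myocardial mask, is within `tolerance` of
the reference intensity and below a hypodensity `ceiling`.

- Reference: fixed mean of the seed voxels (default). A running-mean
  (adaptive) reference is available but is *not* monotone in the tolerance
  — enlarging the tolerance can shift the running mean and exclude voxels
  accepted at a smaller tolerance — so the fixed reference is the default
  to honour the monotonicity guarantee.
- Ceiling default: myocardial median − 2×1.4826×MAD. The interactive
  gray-value choices of the real workflow are unrecorded; all defaults here
  are calibrated on phantoms only.
- `open_radius` (default 0): optional binary opening after growth. With
  the default streak texture, radius-1 opening removes the streak-width
  tendrils along which growth leaks out of high-intensity-factor lesions,
  while leaving compact lesion pools intact; phantom-calibrated analyses
  use tolerance = 4×noise SD with `open_radius=1` and recover ellipsoidal
  lesion volumes within 10% for intensity factors 0.3–0.7. Opening is
  monotone, so tolerance-monotonicity is preserved.

Sparse manual annotation is emulated by `propagate_sparse_seeds`: lesion
outlines on every k-th slice (default 10) become seed voxels; a lesion
thinner than k slices that falls entirely between sampled slices is missed
— an inherent sensitivity limit of sparse seeding.

## LV mass

Sparse contours (every `stride`-th slice plus the first and last nonempty
slices; optionally epicardial-only at the ends, filling the section solid
as when tracing the most basal/apical slices) are interpolated to a dense
mask by linear blending of per-slice signed distance fields — shape-based
interpolation, chosen over nearest-slice copying because intermediate
cross-sections then morph smoothly; contoured slices are reproduced
exactly. Epicardial-only end slices are opt-in (`epi_only_ends`) so that a
stride-1 contour set round-trips the input mask exactly.

M1 sums per-slice areas × slice thickness; M2 counts mask voxels × voxel
volume; on the same dense mask they are identical integers by construction.
Mass = volume × density with density 1.05 g/ml by default (measured for
iodinated myocardium; overridable). Bland–Altman agreement uses
bias = mean(a−b) and limits bias ± 1.96×SD(a−b) with sample SD.

## The synthetic world

`generate_ring_phantom` builds an annulus (optionally an angular sector,
180° mimicking half-transverse LV sections) whose true HA varies linearly
with normalized wall depth between `ha_endo_deg` (+50° default) and
`ha_epi_deg` (−50° default). The texture superimposes short anisotropic
Gaussian streaks (defaults: ~10-voxel length, ~3.6-voxel width as 4σ
extents, amplitude ±60 on a base intensity of 100, density 0.006/voxel ≈ 20
streaks per 15³ neighborhood) elongated along the local fiber direction —
the circumferential vector tilted out of plane by HA about the radial axis.
Disarray regions randomize streak orientations per streak (isotropic 3D by
default, or in-plane random); replacement-fibrosis lesions are ellipsoids
in which the streak texture is *replaced* by a homogeneous intensity of
`intensity_factor` × base — collagen replacing lost myocytes produces a
compact pool of similar gray values, which is what gray-scale region
growing presupposes. Additive Gaussian noise defaults to 5 intensity units
(5% of the myocardium–background contrast). Voxel size defaults to 16 µm,
typical of LV-section micro-CT scans.

Two deliberate idealisations:

- the myocardium–background boundary is a smooth analytic taper
  (`edge_softness`, default 2.5 voxels) rather than a hard voxel cut. A
  hard cut creates z-invariant staircase gradients along the whole surface
  whose energy is purely in-plane, which biases v₃ toward the long axis
  (|HA| → 90°) within a tensor window of the wall surface; the smooth
  radial taper makes boundary gradients purely transmural, which leaves v₃
  untouched;
- no X-ray physics: iodine diffusion gradients, beam hardening, cone-beam
  or ring artifacts are absent. Streak contrast and width are free
  parameters, not fitted to any acquisition.

A green phantom test therefore establishes the correctness and internal
consistency of the estimators on textured, noisy, geometrically faithful
input — not robustness to staining or reconstruction artifacts of real
scanners.

`generate_shell_stack` builds a stack of annular slices with linearly
varying radii (truncated-cone shell) whose analytic volume is the per-slice
continuous annulus area summed over slices — the oracle for the mass
pipeline; voxelisation error is bounded by a one-voxel shell on each
border.

## Statistics

Two-sample comparisons on raw samples: Kolmogorov–Smirnov (distribution
shape across segments), Student's t and Mann–Whitney U (scipy
implementations). Profile-slope comparison reports group mean (SD) of B1, a
two-sample t-test on slopes, and per-depth-bin Mann–Whitney tests on the
binned means. Identical zero-variance groups report statistic 0, p = 1. No
multiple-testing correction is applied, matching the analysis surface this
mirrors. Report bundles (JSON + CSV + PNG) are byte-identical across
re-runs for fixed inputs.

## Known limitations

- Cohort-scale effect sizes (group mean FA, slope or mass differences of
  real hearts) are outside desk-scale reproduction; the tests assert
  directions of effect and estimator accuracy on phantoms instead.
- Wall-depth values near the cut faces of partial rings are distorted
  within ~one wall thickness of the cut.
- The circumferential-myocyte threshold (|HA| < 22.5°) is a configurable
  convention; per-voxel HA dispersion biases the reported fraction a few
  percentage points below the analytic value of a noiseless profile.
- `interpolate_masks` does not extrapolate beyond the first/last contoured
  slice; basal/apical myocardium outside the contoured range is excluded,
  which reproduces the direction (underestimation) of contour-based mass
  relative to actual mass.
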