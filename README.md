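# myofiberct

Quantitative phenotyping of ex-vivo cardiac micro-CT volumes: per-voxel
myocyte orientation by 3D structure-tensor analysis, replacement-fibrosis
volumetry by gray-scale region growing, and left-ventricular (LV) mass
estimation from sparse manual contours.

The package targets the postmortem assessment of hypertrophic
cardiomyopathy (HCM) — a disease defined by hypertrophy, myocyte disarray
and fibrosis — on iodine-stained micro-CT at micrometre, isotropic voxel
sizes. Because such specimens are not redistributable, the package ships a
first-class synthetic-phantom module: every pipeline stage is validated
against annular LV phantoms with a prescribed transmural helix, known
disarray and lesion masks, and closed-form volumes.

## The quantities

For an intensity volume *I* the structure tensor at each voxel is

> J = G_σ ∗ (∇I ∇Iᵀ),  ∇I by central differences,

with eigenvalues λ₁ ≥ λ₂ ≥ λ₃ ≥ 0. The tertiary eigenvector **v₃** (of λ₃)
is the direction of least intensity variation, i.e. the local long axis of
the aggregated myocytes. From it:

- **Helical angle** HA = atan2(v₃·ẑ, v₃·ĉ) ∈ [−90°, 90°] — elevation of the
  myocyte axis out of the local short-axis plane, where ĉ and ẑ are the
  circumferential and long-axis directions of a per-slice LV frame. Normal
  walls rotate from positive HA at the endocardium to negative at the
  epicardium.
- **Fractional anisotropy**
  FA = √(3/2) · ‖λ − λ̄‖ / ‖λ‖ ∈ [0, 1] — 1 for fully oriented texture,
  0 for isotropic (disordered) texture.
- **Myocardial disarray index** MDI = (3 λ_max(⟨v₃v₃ᵀ⟩) − 1)/2 over a
  15×15×15 neighborhood — the nematic order parameter of the orientation
  field: 1 when the neighborhood is collinear, 0 in expectation when
  orientations are isotropically random.

Fibrosis is segmented by seeded 26-connected region growing over hypodense
voxels (within a tolerance of the seed-region intensity and below a global
hypodensity ceiling) and reported in mm³. LV mass is myocardial volume —
from dense masks (M2) or per-slice area sums (M1), reconstructed from
sparse contours by signed-distance interpolation — times a myocardial
density of 1.05 g/ml; agreement between paired mass series is summarised by
Bland–Altman bias and limits of agreement.

## Worked example

```python
import numpy as np
from myofiberct import PhantomSpec, generate_ring_phantom, analyze_orientation

# annular LV phantom, 25-voxel wall, helix +50 deg (endo) -> -50 deg (epi)
spec = PhantomSpec(shape=(48, 120, 120), inner_radius=25, outer_radius=50, seed=7)
vol, truth = generate_ring_phantom(spec)
ana = analyze_orientation(vol, truth.mask())

prof = ana.profiles["whole"]
print(f"HA slope B1: {prof.slope:.1f} deg/depth (R^2 = {prof.r_squared:.3f})")
print(f"mean FA:  {np.mean(ana.fa.valid_values()):.3f}")
print(f"mean MDI: {np.mean(ana.mdi.valid_values()):.3f}")
print(f"circumferential myocytes (|HA| < 22.5 deg): {ana.circumferential_pct:.1f}%")
```

prints

```
HA slope B1: -98.3 deg/depth (R^2 = 0.992)
mean FA:  0.635
mean MDI: 0.864
circumferential myocytes (|HA| < 22.5 deg): 40.6%
```

The fitted transmural slope recovers the prescribed −100°/unit-depth helix;
FA and MDI are high because the texture is fully aligned (injecting
disarray regions lowers both — see `tests/test_acceptance.py`). The
circumferential fraction sits a few points below the analytic 45% of the
linear profile because of per-voxel estimator dispersion at the threshold.

A command-line interface wraps the same pipeline:

```sh
myofiber-ct phantom --config cfg.yaml --out phantom/
myofiber-ct metrics --volume vol.nii.gz --mask mask.nii.gz --out out/
myofiber-ct fibrosis --volume vol.nii.gz --mask mask.nii.gz \
    --outlines outlines.nii.gz --tolerance 20 --out out/
myofiber-ct mass --mask mask.nii.gz --stride 5 --out out/
myofiber-ct all --config cfg.yaml --seed 1 --out report/
```

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from scratch, the maximum MDI over 1,000 random 15³
neighborhoods, the MDI of a perfectly collinear neighborhood, and the mean
recovered helical angle in the innermost-10% and mid-wall depth bins of the
full-scale (200³) linear-helix ring phantom, and writes them as JSON.

See `docs/methods.md` for the model assumptions, parameter defaults and
known limitations.
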