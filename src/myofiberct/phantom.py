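"""Synthetic left-ventricular phantoms with known ground truth.

Real iodinated micro-CT hearts are not redistributable, so every stage of
the pipeline is validated on volumetric phantoms: an annular (or half-ring)
LV cross-section whose anisotropic texture follows a prescribed transmural
helix-angle profile (defaults +50 deg at the endocardium to -50 deg at the
epicardium), with optional randomized-orientation (disarray) regions and
hypodense ellipsoidal lesions (replacement fibrosis); and a stack of
annular slices of known analytic volume for mass validation.

The texture is a superposition of short anisotropic Gaussian "streaks"
elongated along the local fiber direction: the fiber direction is the
circumferential vector tilted out of the slice plane by the helical angle
about the radial axis.  Streaks give the intensity gradients a dominant
orientation transverse to the fiber, which is exactly what structure-tensor
analysis detects.  X-ray physics (iodine diffusion, beam hardening,
reconstruction artifacts) is deliberately not modelled.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import asdict, dataclass, field

import numpy as np

from .io import LVMask, VoxelVolume, write_array, write_volume
from .mass import MYOCARDIAL_DENSITY_G_PER_ML, SliceContours

__all__ = [
    "DisarrayRegion",
    "LesionRegion",
    "PhantomSpec",
    "ShellSpec",
    "PhantomTruth",
    "generate_ring_phantom",
    "generate_shell_stack",
    "sparse_contours",
    "save_phantom",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DisarrayRegion:
    """Spherical region in which streak orientations are randomized.

    ``mode`` is ``random-3d`` (isotropic unit vectors, the default — myocytes
    arranged in random directions) or ``in-plane-random`` (random orientation
    within the short-axis plane).
    """

    center: tuple[float, float, float]  # (long, row, col) voxels
    radius: float
    mode: str = "random-3d"


@dataclass(frozen=True)
class LesionRegion:
    """Hypodense ellipsoid emulating replacement fibrosis.

    Voxel intensities inside the ellipsoid are multiplied by
    ``intensity_factor`` in (0, 1).
    """

    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]
    intensity_factor: float = 0.5


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of a ring phantom; the generator is a pure function
    of this spec (fixed seed => bit-identical output).

    Geometry: axis 0 is the long axis; each slice holds an annulus between
    ``inner_radius`` and ``outer_radius`` (voxels), optionally restricted to
    an angular span (180 deg mimics half-transverse LV sections).  The true
    helical angle varies linearly with normalized wall depth from
    ``ha_endo_deg`` (depth 0) to ``ha_epi_deg`` (depth 1).

    Texture: ``streak_density`` streaks per myocardial voxel (default 0.006,
    i.e. >= ~20 streaks per 15^3 neighborhood); streak length/width are the
    ~4-sigma extents of the anisotropic Gaussian in voxels.  Noise is
    additive Gaussian; the default sigma is 5% of the myocardium–background
    contrast (``base_intensity``).
    """

    shape: tuple[int, int, int] = (200, 200, 200)
    voxel_size_um: float = 16.0
    inner_radius: float = 45.0
    outer_radius: float = 85.0
    angular_span_deg: float = 360.0
    ha_endo_deg: float = 50.0
    ha_epi_deg: float = -50.0
    disarray_regions: tuple[DisarrayRegion, ...] = ()
    lesion_regions: tuple[LesionRegion, ...] = ()
    streak_length: float = 10.0
    streak_width: float = 3.6
    streak_density: float = 0.006
    streak_amplitude: float = 60.0
    base_intensity: float = 100.0
    noise_sigma: float = 5.0
    edge_softness: float = 2.5
    seed: int = 0

    def validate(self) -> None:
        nz, ny, nx = self.shape
        if self.voxel_size_um <= 0:
            raise ValueError("voxel_size_um must be positive")
        if not 0 <= self.inner_radius < self.outer_radius:
            raise ValueError("need 0 <= inner_radius < outer_radius")
        if 2 * self.outer_radius >= min(ny, nx):
            raise ValueError("outer radius does not fit inside the grid")
        for a in (self.ha_endo_deg, self.ha_epi_deg):
            if not -90 <= a <= 90:
                raise ValueError(f"helix-angle endpoint {a} outside [-90, 90]")
        if not 0 < self.angular_span_deg <= 360:
            raise ValueError("angular span must be in (0, 360] degrees")
        for reg in self.disarray_regions:
            if reg.mode not in ("random-3d", "in-plane-random"):
                raise ValueError(f"unknown disarray mode {reg.mode!r}")
            self._check_inside(reg.center, (reg.radius,) * 3, "disarray region")
        for les in self.lesion_regions:
            if not 0 < les.intensity_factor < 1:
                raise ValueError("lesion intensity factor must be in (0, 1)")
            self._check_inside(les.center, les.semi_axes, "lesion region")

    def _check_inside(self, center, extents, what: str) -> None:
        for c, e, s in zip(center, extents, self.shape):
            if c - e < 0 or c + e > s - 1:
                raise ValueError(
                    f"{what} at center {tuple(center)} with extent {tuple(extents)} "
                    f"falls outside grid of shape {self.shape}"
                )


@dataclass(frozen=True)
class ShellSpec:
    """Stack of annular slices (truncated-cone shell) of known volume.

    Radii vary linearly from base to apex; apex radii default to the base
    values (straight cylinder).  ``apex_inner_radius = 0`` closes the cavity
    toward the apex.
    """

    shape: tuple[int, int, int] = (60, 64, 64)
    voxel_size_um: float = 100.0
    outer_radius: float = 20.0
    inner_radius: float = 10.0
    n_slices: int = 50
    apex_outer_radius: float | None = None
    apex_inner_radius: float | None = None
    base_intensity: float = 100.0
    noise_sigma: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if not 0 <= self.inner_radius < self.outer_radius:
            raise ValueError("need 0 <= inner_radius < outer_radius")
        ro1 = self.apex_outer_radius if self.apex_outer_radius is not None else self.outer_radius
        ri1 = self.apex_inner_radius if self.apex_inner_radius is not None else self.inner_radius
        if not 0 <= ri1 < ro1:
            raise ValueError("degenerate apex radii")
        if self.n_slices < 1 or self.n_slices > self.shape[0]:
            raise ValueError("n_slices must fit inside the grid")
        if 2 * max(self.outer_radius, ro1) >= min(self.shape[1:]):
            raise ValueError("outer radius does not fit inside the grid")


@dataclass
class PhantomTruth:
    """Ground truth accompanying a phantom volume."""

    ha_deg: np.ndarray  # prescribed HA per voxel (NaN outside myocardium)
    depth: np.ndarray  # normalized wall depth (NaN outside myocardium)
    myocardial_mask: np.ndarray
    disarray_mask: np.ndarray
    lesion_mask: np.ndarray
    analytic_volume_mm3: float
    analytic_mass_g: float
    center: tuple[float, float]  # in-slice (row, col) ring center
    voxel_size_um: float

    def mask(self) -> LVMask:
        return LVMask(self.myocardial_mask, role="myocardium")


def _smoothstep(x: np.ndarray, width: float) -> np.ndarray:
    """C1 taper: 0 for x <= -width/2, 1 for x >= +width/2, 0.5 at x = 0."""
    if width <= 0:
        return (x >= 0).astype(np.float64)
    t = np.clip(x / width + 0.5, 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


def _fiber_direction(ty: np.ndarray, tx: np.ndarray, ha_rad: np.ndarray) -> np.ndarray:
    """Fiber = circumferential vector tilted out of plane by HA.

    Component order (long, row, col); transmural direction t = (0, ty, tx),
    circumferential c = z x t = (0, -tx, ty), longitudinal z = (1, 0, 0).
    """
    cos_ha = np.cos(ha_rad)
    sin_ha = np.sin(ha_rad)
    return np.stack([sin_ha, -cos_ha * tx, cos_ha * ty], axis=-1)


def generate_ring_phantom(spec: PhantomSpec) -> tuple[VoxelVolume, PhantomTruth]:
    """Generate an annular LV phantom with oriented streak texture.

    Returns the intensity volume and the ground truth (prescribed HA map,
    wall depth, myocardium/disarray/lesion masks, analytic volume and mass).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    nz, ny, nx = spec.shape
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0

    rows, cols = np.mgrid[0:ny, 0:nx].astype(np.float64)
    dy = rows - cy
    dx = cols - cx
    r = np.hypot(dy, dx)
    ring2d = (r >= spec.inner_radius) & (r < spec.outer_radius)
    # Smooth edge taper, a pure function of the continuous radius (and angle,
    # for partial rings).  A hard voxelised cut-off would put staircase
    # gradient energy in the slice plane along the whole boundary, which is
    # z-invariant and therefore biases v3 toward the long axis at the
    # endo-/epicardial surfaces; the smooth taper makes boundary gradients
    # purely transmural, which leaves the tertiary eigenvector untouched.
    alpha2d = _smoothstep(r - spec.inner_radius, spec.edge_softness) * _smoothstep(
        spec.outer_radius - r, spec.edge_softness
    )
    if spec.angular_span_deg < 360:
        theta = np.degrees(np.arctan2(dy, dx)) % 360.0
        ring2d &= theta < spec.angular_span_deg
        # angular taper width equivalent (in degrees) to edge_softness voxels
        # at the mid-wall radius
        w_deg = np.degrees(spec.edge_softness / (0.5 * (spec.inner_radius + spec.outer_radius)))
        alpha2d *= _smoothstep(theta, w_deg) * _smoothstep(spec.angular_span_deg - theta, w_deg)
    mask = np.broadcast_to(ring2d, spec.shape).copy()

    depth2d = np.where(
        ring2d, (r - spec.inner_radius) / (spec.outer_radius - spec.inner_radius), np.nan
    )
    ha2d = spec.ha_endo_deg + (spec.ha_epi_deg - spec.ha_endo_deg) * depth2d
    depth = np.broadcast_to(depth2d, spec.shape).copy()
    ha = np.broadcast_to(ha2d, spec.shape).copy()

    zz, yy, xx = np.mgrid[0:nz, 0:ny, 0:nx].astype(np.float32)
    disarray_mask = np.zeros(spec.shape, dtype=bool)
    for reg in spec.disarray_regions:
        d2 = (
            (zz - reg.center[0]) ** 2 + (yy - reg.center[1]) ** 2 + (xx - reg.center[2]) ** 2
        )
        disarray_mask |= d2 <= reg.radius**2
    lesion_mask = np.zeros(spec.shape, dtype=bool)
    for les in spec.lesion_regions:
        d2 = (
            ((zz - les.center[0]) / les.semi_axes[0]) ** 2
            + ((yy - les.center[1]) / les.semi_axes[1]) ** 2
            + ((xx - les.center[2]) / les.semi_axes[2]) ** 2
        )
        lesion_mask |= d2 <= 1.0
    del zz, yy, xx
    disarray_mask &= mask
    lesion_mask &= mask

    # --- streak texture -------------------------------------------------
    texture = np.zeros(spec.shape, dtype=np.float32)
    mask_idx = np.column_stack(np.nonzero(mask))
    n_streaks = int(round(spec.streak_density * len(mask_idx)))
    if n_streaks > 0:
        picks = rng.integers(0, len(mask_idx), size=n_streaks)
        centers = mask_idx[picks].astype(np.float64)
        centers += rng.uniform(-0.5, 0.5, size=centers.shape)

        c_dy = centers[:, 1] - cy
        c_dx = centers[:, 2] - cx
        c_r = np.hypot(c_dy, c_dx)
        ty = c_dy / np.maximum(c_r, 1e-9)
        tx = c_dx / np.maximum(c_r, 1e-9)
        c_depth = np.clip(
            (c_r - spec.inner_radius) / (spec.outer_radius - spec.inner_radius), 0.0, 1.0
        )
        c_ha = np.radians(spec.ha_endo_deg + (spec.ha_epi_deg - spec.ha_endo_deg) * c_depth)
        dirs = _fiber_direction(ty, tx, c_ha)

        # randomize orientation of streaks whose center lies in a disarray region
        for reg in spec.disarray_regions:
            d2 = ((centers - np.asarray(reg.center)) ** 2).sum(axis=1)
            inside = d2 <= reg.radius**2
            n_in = int(inside.sum())
            if n_in == 0:
                continue
            if reg.mode == "random-3d":
                v = rng.standard_normal((n_in, 3))
                v /= np.linalg.norm(v, axis=1, keepdims=True)
            else:  # in-plane-random
                phi = rng.uniform(0, 2 * np.pi, size=n_in)
                v = np.column_stack([np.zeros(n_in), np.sin(phi), np.cos(phi)])
            dirs[inside] = v

        amps = spec.streak_amplitude * rng.choice([-1.0, 1.0], size=n_streaks)
        sig_l = spec.streak_length / 4.0
        sig_t = spec.streak_width / 4.0
        _render_streaks(texture, centers, dirs, amps, sig_l, sig_t)

    vol = (alpha2d[None].astype(np.float32) * (spec.base_intensity + texture)).astype(np.float32)
    if lesion_mask.any():
        # Replacement fibrosis: collagen replaces the lost myocytes, so the
        # streak texture vanishes inside the lesion and the intensity drops
        # to intensity_factor x base — a compact pool of similar gray values.
        # The most hypodense factor wins where lesions overlap.
        factor_map = np.ones(spec.shape, dtype=np.float32)
        for les in spec.lesion_regions:
            zz, yy, xx = np.mgrid[0:nz, 0:ny, 0:nx].astype(np.float32)
            d2 = (
                ((zz - les.center[0]) / les.semi_axes[0]) ** 2
                + ((yy - les.center[1]) / les.semi_axes[1]) ** 2
                + ((xx - les.center[2]) / les.semi_axes[2]) ** 2
            )
            inside = (d2 <= 1.0) & mask
            factor_map[inside] = np.minimum(factor_map[inside], les.intensity_factor)
            del zz, yy, xx
        lesion_intensity = alpha2d[None].astype(np.float32) * spec.base_intensity * factor_map
        vol = np.where(lesion_mask, lesion_intensity, vol)
    if spec.noise_sigma > 0:
        vol = vol + rng.normal(0.0, spec.noise_sigma, size=spec.shape).astype(np.float32)

    span_frac = spec.angular_span_deg / 360.0
    vs_mm = spec.voxel_size_um / 1000.0
    analytic_vol = (
        span_frac * np.pi * (spec.outer_radius**2 - spec.inner_radius**2) * nz * vs_mm**3
    )
    truth = PhantomTruth(
        ha_deg=np.where(mask, ha, np.nan).astype(np.float32),
        depth=np.where(mask, depth, np.nan).astype(np.float32),
        myocardial_mask=mask,
        disarray_mask=disarray_mask,
        lesion_mask=lesion_mask,
        analytic_volume_mm3=float(analytic_vol),
        analytic_mass_g=float(analytic_vol / 1000.0 * MYOCARDIAL_DENSITY_G_PER_ML),
        center=(cy, cx),
        voxel_size_um=spec.voxel_size_um,
    )
    return VoxelVolume(vol, spec.voxel_size_um), truth


def _render_streaks(texture, centers, dirs, amps, sig_l, sig_t) -> None:
    """Accumulate anisotropic Gaussian streaks into ``texture`` in place."""
    nz, ny, nx = texture.shape
    shape = np.array([nz, ny, nx])
    half = np.ceil(3.0 * sig_l * np.abs(dirs) + 3.0 * sig_t).astype(int)
    lo = np.maximum(np.floor(centers).astype(int) - half, 0)
    hi = np.minimum(np.floor(centers).astype(int) + half + 1, shape)
    inv_2sl2 = 1.0 / (2.0 * sig_l**2)
    inv_2st2 = 1.0 / (2.0 * sig_t**2)
    for k in range(len(centers)):
        (z0, y0, x0), (z1, y1, x1) = lo[k], hi[k]
        if z0 >= z1 or y0 >= y1 or x0 >= x1:
            continue
        pz = np.arange(z0, z1, dtype=np.float32)[:, None, None] - centers[k, 0]
        py = np.arange(y0, y1, dtype=np.float32)[None, :, None] - centers[k, 1]
        px = np.arange(x0, x1, dtype=np.float32)[None, None, :] - centers[k, 2]
        d = dirs[k]
        u = pz * d[0] + py * d[1] + px * d[2]
        rho2 = pz**2 + py**2 + px**2 - u**2
        texture[z0:z1, y0:y1, x0:x1] += amps[k] * np.exp(
            -(u**2 * inv_2sl2 + np.maximum(rho2, 0.0) * inv_2st2)
        )


def generate_shell_stack(spec: ShellSpec) -> tuple[VoxelVolume, PhantomTruth]:
    """Stack of annular slices with a closed-form myocardial volume.

    Slice ``k`` of the shell (0-based within the stack) carries the annulus
    between radii interpolated linearly from base to apex; the analytic
    volume is the per-slice continuous annulus area summed over slices.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    nz, ny, nx = spec.shape
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    ro1 = spec.apex_outer_radius if spec.apex_outer_radius is not None else spec.outer_radius
    ri1 = spec.apex_inner_radius if spec.apex_inner_radius is not None else spec.inner_radius

    rows, cols = np.mgrid[0:ny, 0:nx].astype(np.float64)
    r = np.hypot(rows - cy, cols - cx)
    mask = np.zeros(spec.shape, dtype=bool)
    analytic_area = 0.0
    for k in range(spec.n_slices):
        f = k / (spec.n_slices - 1) if spec.n_slices > 1 else 0.0
        ro = spec.outer_radius + f * (ro1 - spec.outer_radius)
        ri = spec.inner_radius + f * (ri1 - spec.inner_radius)
        mask[k] = (r >= ri) & (r < ro)
        analytic_area += np.pi * (ro**2 - ri**2)
    vs_mm = spec.voxel_size_um / 1000.0
    analytic_vol = analytic_area * vs_mm**3

    vol = np.where(mask, spec.base_intensity, 0.0).astype(np.float32)
    if spec.noise_sigma > 0:
        vol = vol + rng.normal(0.0, spec.noise_sigma, size=spec.shape).astype(np.float32)
    nanmap = np.full(spec.shape, np.nan, dtype=np.float32)
    truth = PhantomTruth(
        ha_deg=nanmap,
        depth=nanmap.copy(),
        myocardial_mask=mask,
        disarray_mask=np.zeros(spec.shape, dtype=bool),
        lesion_mask=np.zeros(spec.shape, dtype=bool),
        analytic_volume_mm3=float(analytic_vol),
        analytic_mass_g=float(analytic_vol / 1000.0 * MYOCARDIAL_DENSITY_G_PER_ML),
        center=(cy, cx),
        voxel_size_um=spec.voxel_size_um,
    )
    return VoxelVolume(vol, spec.voxel_size_um), truth


def sparse_contours(
    mask: LVMask | np.ndarray,
    stride: int,
    epi_only_ends: bool = False,
) -> list[SliceContours]:
    """Extract endo+epi contour regions from every ``stride``-th slice.

    The first and last nonempty slices are always included; with
    ``epi_only_ends`` they carry only the epicardial border (the enclosed
    cavity is treated as myocardium, as when tracing the most basal/apical
    slices).  Empty slices inside the sampled range are skipped with a log
    entry.
    """
    from scipy import ndimage

    if stride < 1:
        raise ValueError("stride must be >= 1")
    arr = mask.data if isinstance(mask, LVMask) else np.asarray(mask, dtype=bool)
    nonempty = np.nonzero(arr.reshape(arr.shape[0], -1).any(axis=1))[0]
    if len(nonempty) == 0:
        raise ValueError("mask has no nonempty slices")
    z0, z1 = int(nonempty[0]), int(nonempty[-1])
    wanted = sorted(set(range(z0, z1 + 1, stride)) | {z0, z1})
    out: list[SliceContours] = []
    for k in wanted:
        sl = arr[k]
        if not sl.any():
            logger.info("slice %d empty, skipped from contour set", k)
            continue
        filled = ndimage.binary_fill_holes(sl)
        endo = filled & ~sl
        if epi_only_ends and k in (z0, z1):
            out.append(SliceContours(index=k, epi=filled, endo=None))
        else:
            out.append(SliceContours(index=k, epi=filled, endo=endo if endo.any() else None))
    return out


def save_phantom(vol: VoxelVolume, truth: PhantomTruth, outdir: str, spec=None) -> None:
    """Persist a phantom: volume + truth maps as NIfTI, JSON sidecar."""
    os.makedirs(outdir, exist_ok=True)
    write_volume(vol, os.path.join(outdir, "volume.nii.gz"))
    vs = vol.voxel_size_um
    for name, arr in [
        ("truth_ha_deg", truth.ha_deg.astype(np.float32)),
        ("truth_depth", truth.depth.astype(np.float32)),
        ("mask_myocardium", truth.myocardial_mask.astype(np.uint8)),
        ("mask_disarray", truth.disarray_mask.astype(np.uint8)),
        ("mask_lesion", truth.lesion_mask.astype(np.uint8)),
    ]:
        write_array(arr, vs, os.path.join(outdir, f"{name}.nii.gz"))
    sidecar = {
        "voxel_size_um": vs,
        "analytic_volume_mm3": truth.analytic_volume_mm3,
        "analytic_mass_g": truth.analytic_mass_g,
        "center_row_col": list(truth.center),
    }
    if spec is not None:
        sidecar["spec"] = asdict(spec)
    with open(os.path.join(outdir, "phantom.json"), "w") as fh:
        json.dump(sidecar, fh, indent=2, sort_keys=True, default=list)
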