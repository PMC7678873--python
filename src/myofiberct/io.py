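"""Volumetric image I/O and basic geometry bookkeeping.

All in-memory volumes use axis order ``(long-axis, row, col)`` — axis 0 runs
from base to apex, axes 1 and 2 span the short-axis (transverse) plane.
Coordinates are 0-based voxel indices; physical units (mm^3, g) are derived
only at reporting time from the isotropic voxel size carried in µm.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np
import tifffile

__all__ = ["VoxelVolume", "LVMask", "read_volume", "write_volume", "crop_to_mask"]


@dataclass
class VoxelVolume:
    """A 3D scalar intensity grid with isotropic voxel size.

    Parameters
    ----------
    data
        3D array of intensities, axis order (long-axis, row, col).
    voxel_size_um
        Isotropic voxel edge length in micrometres, > 0.
    origin
        Voxel-index offset of ``data[0, 0, 0]`` in the coordinate frame of
        the originating (uncropped) volume.
    """

    data: np.ndarray
    voxel_size_um: float
    origin: tuple[int, int, int] = (0, 0, 0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D volume, got shape {self.data.shape}")
        if not self.voxel_size_um > 0:
            raise ValueError(f"voxel_size_um must be positive, got {self.voxel_size_um}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume intensities must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_size_mm(self) -> float:
        return self.voxel_size_um / 1000.0

    @property
    def voxel_volume_mm3(self) -> float:
        return self.voxel_size_mm**3


@dataclass
class LVMask:
    """Binary mask on the same lattice as its companion volume."""

    data: np.ndarray
    role: str = "myocardium"
    origin: tuple[int, int, int] = (0, 0, 0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D mask, got shape {self.data.shape}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


def _is_nifti(path: str) -> bool:
    return path.endswith(".nii") or path.endswith(".nii.gz")


def read_volume(path: str, voxel_size_um: float | None = None) -> VoxelVolume:
    """Read a multi-page TIFF stack or a NIfTI volume.

    NIfTI spacing is taken from the header (mm, converted to µm) and must be
    isotropic; the analysis assumes isotropically reconstructed volumes.
    TIFF carries no reliable 3D spacing, so ``voxel_size_um`` is required.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if _is_nifti(path):
        img = nib.load(path)
        zooms = np.asarray(img.header.get_zooms()[:3], dtype=float)
        if not np.allclose(zooms, zooms[0], rtol=1e-3):
            raise ValueError(
                f"anisotropic NIfTI spacing {tuple(zooms)} mm; this pipeline "
                "requires isotropic voxels"
            )
        size_um = float(zooms[0]) * 1000.0
        if voxel_size_um is not None:
            size_um = float(voxel_size_um)
        data = np.asarray(img.dataobj)
        return VoxelVolume(data=data, voxel_size_um=size_um)
    # TIFF stack: tifffile yields (pages, rows, cols) = (long-axis, row, col)
    if voxel_size_um is None:
        raise ValueError("TIFF stacks carry no 3D spacing: pass voxel_size_um explicitly")
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    return VoxelVolume(data=data, voxel_size_um=float(voxel_size_um))


def write_volume(vol: VoxelVolume, path: str) -> None:
    """Write a volume as NIfTI (.nii/.nii.gz) or multi-page TIFF."""
    write_array(np.asarray(vol.data), vol.voxel_size_um, path)


def write_array(data: np.ndarray, voxel_size_um: float, path: str) -> None:
    """Low-level writer; unlike :class:`VoxelVolume`, accepts NaN values
    (metric maps are NaN outside their validity mask)."""
    if _is_nifti(path):
        mm = voxel_size_um / 1000.0
        affine = np.diag([mm, mm, mm, 1.0])
        img = nib.Nifti1Image(np.asarray(data), affine)
        img.header.set_zooms((mm, mm, mm))
        nib.save(img, path)
    else:
        tifffile.imwrite(path, np.asarray(data))


def write_mask(mask: LVMask, voxel_size_um: float, path: str) -> None:
    """Persist a binary/label mask as an 8-bit NIfTI label volume."""
    vol = VoxelVolume(mask.data.astype(np.uint8), voxel_size_um)
    write_volume(vol, path)


def crop_to_mask(vol: VoxelVolume, mask: LVMask, pad: int = 0) -> tuple[VoxelVolume, LVMask]:
    """Crop volume and mask to the mask bounding box plus ``pad`` voxels.

    The returned objects record the crop offset in ``origin`` so voxel
    coordinates map back to the uncropped frame.
    """
    if pad < 0:
        raise ValueError("pad must be >= 0")
    if vol.shape != mask.shape:
        raise ValueError(f"volume shape {vol.shape} != mask shape {mask.shape}")
    if not mask.data.any():
        raise ValueError("cannot crop to an empty mask")
    idx = np.nonzero(mask.data)
    lo = [max(int(i.min()) - pad, 0) for i in idx]
    hi = [min(int(i.max()) + pad + 1, s) for i, s in zip(idx, vol.shape)]
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    origin = tuple(int(o) + a for o, a in zip(vol.origin, lo))
    return (
        replace(vol, data=vol.data[sl], origin=origin),
        replace(mask, data=mask.data[sl], origin=origin),
    )
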