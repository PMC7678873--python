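"""Structure-tensor analysis of oriented 3D texture.

The per-voxel structure tensor is the Gaussian-windowed second moment of the
intensity gradient, J = G_sigma * (g g^T).  For an elongated texture (myocyte
aggregates in contrast-enhanced micro-CT) the gradients concentrate in the
plane transverse to the texture, so the eigenvector of the *smallest*
eigenvalue — the tertiary eigenvector v3, the direction of least intensity
variation — points along the myocyte long axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io import LVMask, VoxelVolume

__all__ = [
    "OrientationField",
    "compute_gradients",
    "compute_structure_tensor",
    "eigendecompose",
    "orientation_from_volume",
]


@dataclass
class OrientationField:
    """Per-voxel eigenstructure of the structure tensor.

    Attributes
    ----------
    eigenvalues
        Array ``(..., 3)`` sorted descending, λ1 ≥ λ2 ≥ λ3 ≥ 0.
    v3
        Unit tertiary eigenvector ``(..., 3)`` in (long-axis, row, col)
        component order; zero on invalid voxels.
    valid
        Boolean mask of voxels with sufficient gradient energy; invalid
        voxels are excluded from every downstream statistic.
    """

    eigenvalues: np.ndarray
    v3: np.ndarray
    valid: np.ndarray

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.valid.shape


def compute_gradients(vol: VoxelVolume | np.ndarray) -> np.ndarray:
    """Per-voxel intensity gradient by central differences.

    Interior voxels use the central difference (I[i+1] - I[i-1]) / 2; grid
    boundary voxels fall back to one-sided differences.  Returns an array of
    shape ``(*vol.shape, 3)`` with components ordered like the array axes.
    """
    data = vol.data if isinstance(vol, VoxelVolume) else np.asarray(vol)
    data = data.astype(np.float32, copy=False)
    g0, g1, g2 = np.gradient(data)
    return np.stack([g0, g1, g2], axis=-1)


def compute_structure_tensor(gradients: np.ndarray, window_sigma: float = 2.0) -> np.ndarray:
    """Gaussian-windowed outer product of the gradient field.

    Each component of g g^T is smoothed with an isotropic Gaussian of scale
    ``window_sigma`` voxels (``0`` disables smoothing).  The result is a
    symmetric positive-semidefinite 3x3 matrix per voxel, shape
    ``(..., 3, 3)``, float32.
    """
    if window_sigma < 0:
        raise ValueError("window_sigma must be >= 0")
    g = np.asarray(gradients, dtype=np.float32)
    if g.shape[-1] != 3:
        raise ValueError("gradient field must have 3 components on the last axis")
    shape = g.shape[:-1]
    tensor = np.empty(shape + (3, 3), dtype=np.float32)
    for i in range(3):
        for j in range(i, 3):
            prod = g[..., i] * g[..., j]
            if window_sigma > 0:
                prod = ndimage.gaussian_filter(prod, sigma=window_sigma)
            tensor[..., i, j] = prod
            if i != j:
                tensor[..., j, i] = prod
    return tensor


def eigendecompose(
    tensors: np.ndarray,
    mask: LVMask | np.ndarray | None = None,
    energy_eps: float = 1e-4,
) -> OrientationField:
    """Eigen-decompose a symmetric tensor field into an orientation field.

    Eigenvalues are sorted descending and clipped at zero; ``v3`` is the
    eigenvector of the smallest eigenvalue.  Voxels whose tensor trace falls
    below ``energy_eps`` times the robust (99th-percentile) maximum trace
    over the mask are marked invalid — this drops flat background that leaks
    through the mask.
    """
    tensors = np.asarray(tensors)
    if tensors.shape[-2:] != (3, 3):
        raise ValueError("expected a (..., 3, 3) tensor field")
    if not np.allclose(tensors, np.swapaxes(tensors, -1, -2), rtol=1e-4, atol=1e-5):
        raise ValueError("structure tensors must be symmetric")
    shape = tensors.shape[:-2]
    if mask is None:
        mask_arr = np.ones(shape, dtype=bool)
    else:
        mask_arr = mask.data if isinstance(mask, LVMask) else np.asarray(mask, dtype=bool)
    if mask_arr.shape != shape:
        raise ValueError("mask shape does not match tensor field")

    trace = tensors[..., 0, 0] + tensors[..., 1, 1] + tensors[..., 2, 2]
    if mask_arr.any():
        ref = float(np.percentile(trace[mask_arr], 99.0))
    else:
        ref = 0.0
    if ref <= 0:
        valid = np.zeros(shape, dtype=bool)
    else:
        valid = mask_arr & (trace >= energy_eps * ref)

    eigenvalues = np.zeros(shape + (3,), dtype=np.float32)
    v3 = np.zeros(shape + (3,), dtype=np.float32)
    if valid.any():
        sel = tensors[valid].astype(np.float64)
        w, v = np.linalg.eigh(sel)  # ascending eigenvalues
        eigenvalues[valid] = np.clip(w[:, ::-1], 0.0, None)
        vecs = v[:, :, 0]  # eigenvector of the smallest eigenvalue
        vecs /= np.linalg.norm(vecs, axis=1, keepdims=True)
        v3[valid] = vecs
    return OrientationField(eigenvalues=eigenvalues, v3=v3, valid=valid)


def orientation_from_volume(
    vol: VoxelVolume,
    mask: LVMask,
    window_sigma: float = 2.0,
    energy_eps: float = 1e-4,
) -> OrientationField:
    """Convenience pipeline: gradients -> structure tensor -> eigenstructure."""
    grads = compute_gradients(vol)
    tensors = compute_structure_tensor(grads, window_sigma=window_sigma)
    return eigendecompose(tensors, mask, energy_eps=energy_eps)
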