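"""Per-voxel myocyte-orientation metrics.

From the tertiary eigenvector field and the left-ventricular geometry this
module derives the metrics used to phenotype myocardial architecture:

* **helical angle (HA)** — elevation of the myocyte long axis out of the
  local short-axis (transmural–circumferential) plane, in degrees; positive
  toward the endocardium, negative toward the epicardium in normal hearts;
* **fractional anisotropy (FA)** — normalised RMS deviation of the three
  structure-tensor eigenvalues from their mean, in [0, 1];
* **myocardial disarray index (MDI)** — collinearity of v3 over a cubic
  neighborhood (default 15^3 voxels), 1 for perfectly aligned myocytes and
  0 in expectation for isotropically random orientations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.measure import CircleModel, ransac

from .io import LVMask
from .tensor import OrientationField

__all__ = [
    "LocalFrame",
    "MetricMap",
    "estimate_slice_center",
    "build_local_frame",
    "helical_angle",
    "fractional_anisotropy",
    "fa_from_eigenvalues",
    "disarray_index",
    "mdi",
    "circumferential_fraction",
]

_LONG_AXIS = np.array([1.0, 0.0, 0.0])  # axis 0 = base -> apex


@dataclass
class MetricMap:
    """Scalar per-voxel map restricted to the analysed mask.

    ``values`` is NaN wherever ``valid`` is False; statistics must use
    :meth:`valid_values`.
    """

    values: np.ndarray
    name: str
    valid: np.ndarray

    def valid_values(self) -> np.ndarray:
        return self.values[self.valid]

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape


@dataclass
class LocalFrame:
    """Per-voxel orthonormal transmural / circumferential / longitudinal triad.

    ``transmural`` points radially outward from the slice LV centroid,
    ``longitudinal`` along the long axis (axis 0), and
    ``circumferential = longitudinal x transmural``.
    """

    transmural: np.ndarray
    circumferential: np.ndarray
    longitudinal: np.ndarray
    valid: np.ndarray
    centers: dict[int, tuple[float, float]]


def estimate_slice_center(mask2d: np.ndarray, rng_seed: int = 0) -> tuple[float, float] | None:
    """Estimate the LV center of a single short-axis mask slice.

    A full ring encloses its cavity, whose centroid is the center.  A
    partial (e.g. half-) ring has no enclosed hole, so the center is
    recovered by a RANSAC circle fit to the outer boundary — the epicardial
    arc dominates the consensus while the straight cut edges are rejected
    as outliers.  Returns ``(row, col)`` or None for degenerate slices.
    """
    mask2d = np.asarray(mask2d, dtype=bool)
    n = int(mask2d.sum())
    if n < 8:
        return None
    filled = ndimage.binary_fill_holes(mask2d)
    hole = filled & ~mask2d
    if hole.any():
        r, c = np.nonzero(hole)
        return float(r.mean()), float(c.mean())
    boundary = filled & ~ndimage.binary_erosion(filled)
    pts = np.column_stack(np.nonzero(boundary)).astype(float)
    if len(pts) < 10:
        r, c = np.nonzero(mask2d)
        return float(r.mean()), float(c.mean())
    try:
        model, inliers = ransac(
            pts,
            CircleModel,
            min_samples=3,
            residual_threshold=1.0,
            max_trials=300,
            rng=rng_seed,
        )
    except Exception:
        model = None
    if model is None or not np.all(np.isfinite(model.center)):
        r, c = np.nonzero(mask2d)
        return float(r.mean()), float(c.mean())
    cy, cx = model.center
    return float(cy), float(cx)


def build_local_frame(
    mask: LVMask | np.ndarray,
    centers: dict[int, tuple[float, float]] | None = None,
) -> LocalFrame:
    """Build the per-voxel transmural/circumferential/longitudinal triad.

    The center of each slice is estimated from the mask unless supplied in
    ``centers`` (slice index -> (row, col)).  Slices whose mask is too small
    to define a center are excluded from the frame's validity mask.
    """
    mask_arr = mask.data if isinstance(mask, LVMask) else np.asarray(mask, dtype=bool)
    if not mask_arr.any():
        raise ValueError("mask is empty")
    shape = mask_arr.shape
    t = np.zeros(shape + (3,), dtype=np.float32)
    c = np.zeros(shape + (3,), dtype=np.float32)
    z = np.zeros(shape + (3,), dtype=np.float32)
    valid = np.zeros(shape, dtype=bool)
    used_centers: dict[int, tuple[float, float]] = {}

    rows, cols = np.mgrid[0 : shape[1], 0 : shape[2]].astype(np.float32)
    for k in range(shape[0]):
        sl = mask_arr[k]
        if not sl.any():
            continue
        center = centers.get(k) if centers is not None else None
        if center is None:
            center = estimate_slice_center(sl)
        if center is None:
            continue
        cy, cx = center
        used_centers[k] = (cy, cx)
        dy = rows - cy
        dx = cols - cx
        r = np.hypot(dy, dx)
        ok = sl & (r > 1e-6)
        ty = dy / np.maximum(r, 1e-6)
        tx = dx / np.maximum(r, 1e-6)
        t[k, ..., 1] = np.where(ok, ty, 0.0)
        t[k, ..., 2] = np.where(ok, tx, 0.0)
        # c = z x t with component order (long, row, col): (1,0,0) x (0,ty,tx)
        c[k, ..., 1] = np.where(ok, -tx, 0.0)
        c[k, ..., 2] = np.where(ok, ty, 0.0)
        z[k, ..., 0] = np.where(ok, 1.0, 0.0)
        valid[k] = ok
    return LocalFrame(transmural=t, circumferential=c, longitudinal=z, valid=valid, centers=used_centers)


def helical_angle(orient: OrientationField, frame: LocalFrame) -> MetricMap:
    """Helical angle of v3 with respect to the local circumferential plane.

    v3 is an orientation (sign-free), so it is first sign-fixed to have a
    non-negative circumferential component (longitudinal component used as
    the tie-break when v3 is nearly orthogonal to the circumferential
    direction).  HA = atan2(v3 . z, v3 . c) in degrees, in [-90, 90]; an
    exact +/-90 tie maps to +90.
    """
    valid = orient.valid & frame.valid
    vc = np.einsum("...i,...i->...", orient.v3, frame.circumferential)
    vz = np.einsum("...i,...i->...", orient.v3, frame.longitudinal)
    tiny = np.abs(vc) < 1e-3
    # sign-fix: |vc| in the generic case; |vz| when v3 is (near) in-plane-normal
    vc_f = np.abs(vc)
    vz_f = np.where(tiny, np.abs(vz), np.sign(vc) * vz)
    ha = np.degrees(np.arctan2(vz_f, vc_f)).astype(np.float32)
    ha[~valid] = np.nan
    return MetricMap(values=ha, name="HA", valid=valid)


def fa_from_eigenvalues(l1, l2, l3):
    """Fractional anisotropy of one eigenvalue triple (or arrays thereof).

    FA = sqrt(3/2) * ||lambda - mean(lambda)|| / ||lambda||, 0 when all
    eigenvalues vanish.  Always in [0, 1].
    """
    l1 = np.asarray(l1, dtype=np.float64)
    l2 = np.asarray(l2, dtype=np.float64)
    l3 = np.asarray(l3, dtype=np.float64)
    # difference form of 3/2 * sum((l - mean)^2): exact 0 for equal triples
    num2 = 0.5 * ((l1 - l2) ** 2 + (l2 - l3) ** 2 + (l3 - l1) ** 2)
    den2 = l1**2 + l2**2 + l3**2
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.where(den2 > 0, np.sqrt(num2 / np.maximum(den2, np.finfo(float).tiny)), 0.0)
    return np.clip(fa, 0.0, 1.0)


def fractional_anisotropy(orient: OrientationField) -> MetricMap:
    """FA map of an orientation field (NaN on invalid voxels)."""
    ev = orient.eigenvalues
    fa = fa_from_eigenvalues(ev[..., 0], ev[..., 1], ev[..., 2]).astype(np.float32)
    fa[~orient.valid] = np.nan
    return MetricMap(values=fa, name="FA", valid=orient.valid.copy())


def mdi(vectors: np.ndarray) -> float:
    """Disarray index of a set of orientation vectors.

    The mean dyadic tensor D = <v v^T> is sign-invariant; its largest
    eigenvalue is 1 for perfectly collinear vectors and 1/3 in expectation
    for isotropically random ones.  MDI = (3 lambda_max(D) - 1) / 2 rescales
    this to [0, 1].
    """
    v = np.asarray(vectors, dtype=np.float64)
    if v.ndim != 2 or v.shape[1] != 3 or len(v) == 0:
        raise ValueError("expected a nonempty (n, 3) array of vectors")
    norms = np.linalg.norm(v, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("zero vector in neighborhood")
    v = v / norms
    d = (v.T @ v) / len(v)
    lam_max = float(np.linalg.eigvalsh(d)[-1])
    return float(np.clip((3.0 * lam_max - 1.0) / 2.0, 0.0, 1.0))


def disarray_index(
    orient: OrientationField,
    neighborhood: int = 15,
    min_valid_fraction: float = 0.1,
) -> MetricMap:
    """Myocardial disarray index over a cubic neighborhood (default 15^3).

    Per voxel the mean dyadic tensor of v3 over the valid voxels of the
    neighborhood is formed and MDI = (3 lambda_max - 1) / 2, clamped to
    [0, 1].  Voxels with fewer than ``min_valid_fraction`` valid neighbors
    (window positions outside the grid count as invalid) carry no value.
    """
    if neighborhood < 3 or neighborhood % 2 == 0:
        raise ValueError("neighborhood must be odd and >= 3")
    v = orient.v3.astype(np.float32)
    valid_f = orient.valid.astype(np.float32)
    size = neighborhood
    frac = ndimage.uniform_filter(valid_f, size=size, mode="constant", cval=0.0)
    enough = frac >= min_valid_fraction
    out_valid = orient.valid & enough

    # accumulate the 6 unique dyad components, normalised by the valid count
    comps = {}
    for i in range(3):
        for j in range(i, 3):
            s = ndimage.uniform_filter(v[..., i] * v[..., j], size=size, mode="constant", cval=0.0)
            comps[(i, j)] = s
    values = np.full(orient.shape, np.nan, dtype=np.float32)
    if out_valid.any():
        denom = frac[out_valid]
        d = np.empty((int(out_valid.sum()), 3, 3), dtype=np.float64)
        for i in range(3):
            for j in range(i, 3):
                d[:, i, j] = comps[(i, j)][out_valid] / denom
                d[:, j, i] = d[:, i, j]
        lam_max = np.linalg.eigvalsh(d)[:, -1]
        values[out_valid] = np.clip((3.0 * lam_max - 1.0) / 2.0, 0.0, 1.0)
    return MetricMap(values=values, name="MDI", valid=out_valid)


def circumferential_fraction(ha: MetricMap, threshold_deg: float = 22.5) -> float:
    """Percentage of valid voxels whose |HA| lies below ``threshold_deg``."""
    if not 0 < threshold_deg < 90:
        raise ValueError("threshold must be in (0, 90) degrees")
    vals = ha.valid_values()
    if vals.size == 0:
        raise ValueError("no valid helical-angle voxels")
    return float(100.0 * np.mean(np.abs(vals) < threshold_deg))
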