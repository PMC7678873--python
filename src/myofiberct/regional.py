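"""Regional analysis of the LV cross-section.

The short-axis myocardium is partitioned into 5 named angular segments
(septal, posterior-septal, posterior, posterior-lateral, lateral), metric
histograms are computed per segment, and helical-angle transmural profiles
(binned by normalized wall depth, 0 = endocardium, 1 = epicardium) are
summarised by the slope B1 and linearity R^2 of an ordinary least-squares
fit on the binned means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .io import LVMask
from .metrics import MetricMap, estimate_slice_center

__all__ = [
    "SEGMENT_NAMES",
    "SegmentLabels",
    "TransmuralProfile",
    "define_segments",
    "wall_depth",
    "metric_histogram",
    "transmural_profile",
]

SEGMENT_NAMES = ("septal", "posterior-septal", "posterior", "posterior-lateral", "lateral")


@dataclass
class SegmentLabels:
    """Per-voxel segment labels 1..5 (0 = unlabelled), septal first."""

    labels: np.ndarray
    names: tuple[str, ...]
    boundaries_deg: np.ndarray
    centers: dict[int, tuple[float, float]]

    def voxels(self, name: str) -> np.ndarray:
        return self.labels == (self.names.index(name) + 1)


@dataclass
class TransmuralProfile:
    """Binned HA transmural profile of one segment plus its linear fit."""

    segment: str
    bin_centers: np.ndarray
    mean: np.ndarray  # NaN for empty bins
    sd: np.ndarray
    n: np.ndarray
    slope: float  # B1, degrees per unit depth
    intercept: float
    r_squared: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "segment": self.segment,
                "depth": self.bin_centers,
                "mean": self.mean,
                "sd": self.sd,
                "n": self.n,
            }
        )


def _slice_centers(mask_arr: np.ndarray, centers=None) -> dict[int, tuple[float, float]]:
    out: dict[int, tuple[float, float]] = {}
    for k in range(mask_arr.shape[0]):
        if not mask_arr[k].any():
            continue
        c = centers.get(k) if centers is not None else None
        if c is None:
            c = estimate_slice_center(mask_arr[k])
        if c is not None:
            out[k] = c
    return out


def _mask_angular_span(angles_deg: np.ndarray) -> tuple[float, float]:
    """Occupied angular interval of a (possibly partial) ring.

    Finds the largest empty angular gap on the circle (1-degree bins); the
    occupied span is its complement.  A full ring returns (0, 360).
    """
    bins = np.zeros(360, dtype=bool)
    bins[np.floor(angles_deg % 360).astype(int) % 360] = True
    if bins.all():
        return 0.0, 360.0
    empty = ~bins
    # longest circular run of empty bins
    idx = np.nonzero(empty)[0]
    doubled = np.r_[empty, empty]
    best_len, best_end = 0, 0
    run = 0
    for i in range(len(doubled)):
        run = run + 1 if doubled[i] else 0
        if run > best_len:
            best_len, best_end = run, i
    gap_start = (best_end - best_len + 1) % 360
    start = (gap_start + best_len) % 360
    span = 360 - best_len
    return float(start), float(start + span)


def define_segments(
    mask: LVMask | np.ndarray,
    boundaries_deg: np.ndarray | None = None,
    centers: dict[int, tuple[float, float]] | None = None,
) -> SegmentLabels:
    """Assign each myocardial voxel to one of 5 contiguous angular sectors.

    ``boundaries_deg`` is a monotone array of 6 angles (degrees, measured
    about the slice centroid from the +col axis, counter-clockwise in
    (row, col)); by default the mask's occupied angular span is divided into
    5 equal sectors (36 deg each on a half-ring, 72 deg on a full ring).
    Raises if the sectors fail to cover the mask.
    """
    arr = mask.data if isinstance(mask, LVMask) else np.asarray(mask, dtype=bool)
    if not arr.any():
        raise ValueError("mask is empty")
    ctrs = _slice_centers(arr, centers)
    shape = arr.shape
    rows, cols = np.mgrid[0 : shape[1], 0 : shape[2]].astype(np.float64)
    angle = np.full(shape, np.nan)
    for k, (cy, cx) in ctrs.items():
        ang = np.degrees(np.arctan2(rows - cy, cols - cx)) % 360.0
        angle[k] = np.where(arr[k], ang, np.nan)
    voxel_angles = angle[arr & np.isfinite(angle)]

    if boundaries_deg is None:
        start, end = _mask_angular_span(voxel_angles)
        boundaries = np.linspace(start, end, 6)
    else:
        boundaries = np.asarray(boundaries_deg, dtype=float)
        if boundaries.shape != (6,) or np.any(np.diff(boundaries) <= 0):
            raise ValueError("boundaries_deg must be 6 strictly increasing angles")
        if boundaries[-1] - boundaries[0] > 360 + 1e-9:
            raise ValueError("sector boundaries span more than 360 degrees")

    rel = (angle - boundaries[0]) % 360.0
    total = boundaries[-1] - boundaries[0]
    edges = boundaries - boundaries[0]
    labels = np.zeros(shape, dtype=np.int8)
    inside = arr & np.isfinite(angle)
    seg = np.searchsorted(edges[1:-1], rel[inside], side="right") + 1
    covered = rel[inside] <= total + 1e-6
    # voxels exactly at / within rounding of the end boundary join the last sector
    lab = np.where(covered, np.minimum(seg, 5), 0).astype(np.int8)
    labels[inside] = lab
    uncovered = int(np.count_nonzero(lab == 0))
    if uncovered:
        raise ValueError(f"{uncovered} myocardial voxels not covered by the sectors")
    return SegmentLabels(labels=labels, names=SEGMENT_NAMES, boundaries_deg=boundaries, centers=ctrs)


def wall_depth(
    mask: LVMask | np.ndarray,
    centers: dict[int, tuple[float, float]] | None = None,
) -> np.ndarray:
    """Normalised transmural wall depth per myocardial voxel.

    Per slice, depth = d_endo / (d_endo + d_epi), where d_endo and d_epi are
    Euclidean distances to the endocardial and epicardial boundary regions.
    For a full ring the two are told apart by connectivity (the cavity does
    not touch the image border); for a partial ring the complement is split
    radially about the estimated center, restricted to the mask's angular
    span so the cut faces of a half-ring do not act as boundary.
    Returns an array with NaN outside the mask.
    """
    arr = mask.data if isinstance(mask, LVMask) else np.asarray(mask, dtype=bool)
    if not arr.any():
        raise ValueError("mask is empty")
    ctrs = _slice_centers(arr, centers)
    shape = arr.shape
    depth = np.full(shape, np.nan, dtype=np.float32)
    rows, cols = np.mgrid[0 : shape[1], 0 : shape[2]].astype(np.float64)
    for k in range(shape[0]):
        sl = arr[k]
        if not sl.any():
            continue
        comp = ~sl
        lab, nlab = ndimage.label(comp)
        border_labels = set(np.unique(np.r_[lab[0, :], lab[-1, :], lab[:, 0], lab[:, -1]]))
        border_labels.discard(0)
        cavity = comp & ~np.isin(lab, sorted(border_labels))
        if cavity.any():
            endo_set = cavity
            epi_set = comp & ~cavity
        else:
            if k not in ctrs:
                raise ValueError(f"cannot identify wall boundaries on slice {k}")
            cy, cx = ctrs[k]
            r = np.hypot(rows - cy, cols - cx)
            r_mid = float(np.median(r[sl]))
            ang = np.degrees(np.arctan2(rows - cy, cols - cx)) % 360.0
            occupied = np.zeros(360, dtype=bool)
            occupied[np.floor(ang[sl]).astype(int) % 360] = True
            occupied = occupied | np.roll(occupied, 1) | np.roll(occupied, -1)
            in_span = occupied[np.floor(ang).astype(int) % 360]
            endo_set = comp & in_span & (r < r_mid)
            epi_set = comp & in_span & (r >= r_mid)
        if not endo_set.any() or not epi_set.any():
            raise ValueError(f"cannot identify wall boundaries on slice {k}")
        d_endo = ndimage.distance_transform_edt(~endo_set)
        d_epi = ndimage.distance_transform_edt(~epi_set)
        with np.errstate(invalid="ignore"):
            d = d_endo / (d_endo + d_epi)
        depth[k][sl] = d[sl]
    return depth


def metric_histogram(
    metric: MetricMap,
    labels: SegmentLabels | None = None,
    bins: int = 50,
    value_range: tuple[float, float] | None = None,
) -> dict[str, dict]:
    """Normalised (density) histograms per segment plus the whole section.

    All regions share the same bin edges, so the whole-section histogram is
    exactly the voxel-weighted combination of the segment histograms.
    """
    valid = metric.valid.copy()
    if labels is not None:
        valid &= labels.labels > 0
    vals = metric.values[valid]
    if vals.size == 0:
        raise ValueError("no valid voxels to histogram")
    if value_range is None:
        value_range = (float(np.nanmin(vals)), float(np.nanmax(vals)))
        if value_range[0] == value_range[1]:
            value_range = (value_range[0] - 0.5, value_range[1] + 0.5)
    out: dict[str, dict] = {}
    dens, edges = np.histogram(vals, bins=bins, range=value_range, density=True)
    out["whole"] = {"density": dens, "edges": edges, "n": int(vals.size)}
    if labels is not None:
        for i, name in enumerate(labels.names, start=1):
            sel = valid & (labels.labels == i)
            v = metric.values[sel]
            if v.size == 0:
                out[name] = {"density": None, "edges": edges, "n": 0}
                continue
            d, _ = np.histogram(v, bins=bins, range=value_range, density=True)
            out[name] = {"density": d, "edges": edges, "n": int(v.size)}
    return out


def _fit_profile(centers: np.ndarray, means: np.ndarray) -> tuple[float, float, float]:
    ok = np.isfinite(means)
    if ok.sum() < 2:
        return float("nan"), float("nan"), 0.0
    res = stats.linregress(centers[ok], means[ok])
    r2 = res.rvalue**2
    if not np.isfinite(r2):  # constant profile: slope 0, linearity reported as 0
        r2 = 0.0
    return float(res.slope), float(res.intercept), float(r2)


def transmural_profile(
    ha: MetricMap,
    depth: np.ndarray,
    labels: SegmentLabels | None = None,
    n_bins: int = 10,
) -> dict[str, TransmuralProfile]:
    """Mean/SD of HA per wall-depth bin, with OLS slope B1 and R^2.

    The regression runs on the binned means (empty bins are carried as
    missing and excluded).  Returns one profile per segment, plus the whole
    section under the key ``"whole"``.
    """
    if n_bins < 2:
        raise ValueError("need at least 2 depth bins")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    bin_centers = 0.5 * (edges[:-1] + edges[1:])
    regions: dict[str, np.ndarray] = {"whole": np.ones(ha.shape, dtype=bool)}
    if labels is not None:
        for i, name in enumerate(labels.names, start=1):
            regions[name] = labels.labels == i

    out: dict[str, TransmuralProfile] = {}
    base_valid = ha.valid & np.isfinite(depth)
    for name, region in regions.items():
        sel = base_valid & region
        d = depth[sel]
        v = ha.values[sel]
        idx = np.clip(np.digitize(d, edges) - 1, 0, n_bins - 1)
        mean = np.full(n_bins, np.nan)
        sd = np.full(n_bins, np.nan)
        n = np.zeros(n_bins, dtype=int)
        for b in range(n_bins):
            vb = v[idx == b]
            n[b] = vb.size
            if vb.size:
                mean[b] = vb.mean()
                sd[b] = vb.std(ddof=1) if vb.size > 1 else 0.0
        slope, intercept, r2 = _fit_profile(bin_centers, mean)
        out[name] = TransmuralProfile(
            segment=name,
            bin_centers=bin_centers,
            mean=mean,
            sd=sd,
            n=n,
            slope=slope,
            intercept=intercept,
            r_squared=r2,
        )
    return out
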