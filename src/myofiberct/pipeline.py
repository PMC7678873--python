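"""End-to-end orientation analysis of a volume + myocardial mask.

Chains the stages in their canonical order: structure tensor ->
eigen-decomposition -> local frame -> HA / FA / MDI maps -> wall depth,
segments, histograms and transmural profiles.  Used by the command-line
interface and convenient for scripted analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import LVMask, VoxelVolume
from .metrics import (
    LocalFrame,
    MetricMap,
    build_local_frame,
    circumferential_fraction,
    disarray_index,
    fractional_anisotropy,
    helical_angle,
)
from .regional import SegmentLabels, TransmuralProfile, define_segments, metric_histogram, transmural_profile, wall_depth
from .tensor import OrientationField, orientation_from_volume

__all__ = ["OrientationAnalysis", "analyze_orientation"]


@dataclass
class OrientationAnalysis:
    """All per-voxel and regional outputs of one orientation run."""

    orient: OrientationField
    frame: LocalFrame
    ha: MetricMap
    fa: MetricMap
    mdi: MetricMap | None
    depth: np.ndarray
    labels: SegmentLabels
    profiles: dict[str, TransmuralProfile]
    histograms: dict[str, dict]
    circumferential_pct: float
    params: dict = field(default_factory=dict)


def analyze_orientation(
    vol: VoxelVolume,
    mask: LVMask,
    window_sigma: float = 2.0,
    energy_eps: float = 1e-4,
    mdi_neighborhood: int = 15,
    compute_mdi: bool = True,
    n_depth_bins: int = 10,
    circ_threshold_deg: float = 22.5,
    segment_boundaries_deg: np.ndarray | None = None,
) -> OrientationAnalysis:
    """Run the full structure-tensor orientation analysis on one volume."""
    orient = orientation_from_volume(vol, mask, window_sigma=window_sigma, energy_eps=energy_eps)
    frame = build_local_frame(mask)
    ha = helical_angle(orient, frame)
    fa = fractional_anisotropy(orient)
    mdi_map = disarray_index(orient, neighborhood=mdi_neighborhood) if compute_mdi else None
    depth = wall_depth(mask, centers=frame.centers)
    labels = define_segments(mask, boundaries_deg=segment_boundaries_deg, centers=frame.centers)
    profiles = transmural_profile(ha, depth, labels=labels, n_bins=n_depth_bins)
    histograms = {"HA": metric_histogram(ha, labels, value_range=(-90.0, 90.0))}
    histograms["FA"] = metric_histogram(fa, labels, value_range=(0.0, 1.0))
    if mdi_map is not None:
        histograms["MDI"] = metric_histogram(mdi_map, labels, value_range=(0.0, 1.0))
    return OrientationAnalysis(
        orient=orient,
        frame=frame,
        ha=ha,
        fa=fa,
        mdi=mdi_map,
        depth=depth,
        labels=labels,
        profiles=profiles,
        histograms=histograms,
        circumferential_pct=circumferential_fraction(ha, circ_threshold_deg),
        params={
            "window_sigma": window_sigma,
            "energy_eps": energy_eps,
            "mdi_neighborhood": mdi_neighborhood,
            "n_depth_bins": n_depth_bins,
            "circ_threshold_deg": circ_threshold_deg,
        },
    )
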