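"""Region-growing lesion segmentation and volumetry."""

import numpy as np
import pytest

from myofiberct import (
    generate_ring_phantom,
    lesion_volume,
    propagate_sparse_seeds,
    region_grow,
)
from myofiberct.fibrosis import default_hypodensity_ceiling

from conftest import lesion_spec

# phantom-calibrated growth settings (see docs/methods.md): tolerance of
# 4 noise SD, opening of radius 1 to cut streak-width tendrils
TOL = 20.0
OPEN = 1


class TestRegionGrow:
    def test_lesion_recovery_within_ten_percent(self, lesion_phantom):
        spec, vol, truth = lesion_phantom
        seeds = propagate_sparse_seeds(truth.lesion_mask, k=10, mask=truth.mask())
        seg = region_grow(vol, truth.mask(), seeds, tolerance=TOL, open_radius=OPEN)
        assert seg.n_voxels == pytest.approx(truth.lesion_mask.sum(), rel=0.10)

    def test_zero_tolerance_noiseless_exact_set(self):
        import dataclasses

        spec = dataclasses.replace(lesion_spec(0.5), noise_sigma=0.0, streak_density=0.0)
        vol, truth = generate_ring_phantom(spec)
        # noiseless + textureless: the lesion interior is exactly
        # factor * base; seed at center grows to the equal-intensity set
        center = tuple(np.array(np.nonzero(truth.lesion_mask)).mean(axis=1).astype(int))
        seg = region_grow(vol, truth.mask(), [center], tolerance=0.0)
        grown = vol.data[seg.mask]
        assert np.all(grown == vol.data[center])
        assert seg.n_voxels > 0.5 * truth.lesion_mask.sum()

    def test_no_lesion_empty_segmentation(self, aligned_small):
        _, vol, truth = aligned_small
        seed = tuple(np.argwhere(truth.myocardial_mask)[0])
        with pytest.warns(UserWarning, match="no voxels"):
            seg = region_grow(vol, truth.mask(), [seed], tolerance=10.0,
                              ceiling=float(vol.data[truth.myocardial_mask].min() - 1))
        assert seg.n_voxels == 0

    def test_seed_outside_mask_rejected(self, lesion_phantom):
        _, vol, truth = lesion_phantom
        with pytest.raises(ValueError, match="outside"):
            region_grow(vol, truth.mask(), [(0, 0, 0)], tolerance=5.0)

    def test_tolerance_monotonicity(self, lesion_phantom):
        """Growing tolerance never shrinks the segmented set."""
        spec, vol, truth = lesion_phantom
        seeds = propagate_sparse_seeds(truth.lesion_mask, k=10, mask=truth.mask())
        prev = None
        for tol in (5.0, 10.0, 15.0, 20.0, 25.0):
            seg = region_grow(vol, truth.mask(), seeds, tolerance=tol, open_radius=OPEN)
            if prev is not None:
                assert np.all(seg.mask[prev])  # superset of the previous set
            prev = seg.mask

    def test_recovery_across_intensity_factors(self):
        """10% volume recovery for factors 0.3-0.7 at default noise."""
        for factor in (0.3, 0.5, 0.7):
            spec = lesion_spec(factor)
            vol, truth = generate_ring_phantom(spec)
            seeds = propagate_sparse_seeds(truth.lesion_mask, k=10, mask=truth.mask())
            seg = region_grow(vol, truth.mask(), seeds, tolerance=TOL, open_radius=OPEN)
            assert seg.n_voxels == pytest.approx(truth.lesion_mask.sum(), rel=0.10), factor

    def test_interstitial_like_texture_not_segmented(self, aligned_small):
        """Thin low-contrast texture modulation (the streaks themselves)
        yields no segmentation at the default ceiling: every normal
        myocardial seed lies above it."""
        _, vol, truth = aligned_small
        data = vol.data
        med = np.median(data[truth.myocardial_mask])
        seeds = np.argwhere(truth.myocardial_mask & (np.abs(data - med) < 1.0))[:5]
        with pytest.warns(UserWarning, match="no voxels"):
            seg = region_grow(vol, truth.mask(), seeds, tolerance=TOL, open_radius=OPEN)
        assert seg.n_voxels == 0


class TestSparseSeeds:
    def test_k_equals_one_matches_dense_segmentation(self, lesion_phantom):
        spec, vol, truth = lesion_phantom
        s1 = propagate_sparse_seeds(truth.lesion_mask, k=1, mask=truth.mask())
        dense_seeds = np.argwhere(truth.lesion_mask)
        seg1 = region_grow(vol, truth.mask(), s1, tolerance=TOL, open_radius=OPEN)
        seg_dense = region_grow(vol, truth.mask(), dense_seeds, tolerance=TOL, open_radius=OPEN)
        assert np.array_equal(seg1.mask, seg_dense.mask)

    def test_k_ten_spans_21_slice_lesion_within_ten_percent(self, lesion_phantom):
        _, vol, truth = lesion_phantom
        seeds = propagate_sparse_seeds(truth.lesion_mask, k=10, mask=truth.mask())
        assert len(np.unique(seeds[:, 0])) >= 2  # 21-slice lesion: >= 2 seeded slices
        seg = region_grow(vol, truth.mask(), seeds, tolerance=TOL, open_radius=OPEN)
        assert seg.n_voxels == pytest.approx(truth.lesion_mask.sum(), rel=0.10)

    def test_lesion_thinner_than_k_missed(self):
        # sampling starts at the first outline slice (0 here); a 3-slice
        # lesion sitting entirely between sampled slices contributes nothing
        outlines = np.zeros((30, 8, 8), dtype=bool)
        outlines[0, 0, 0] = True  # anchor outline defining the sampling grid
        outlines[15:18, 3, 3] = True
        seeds = propagate_sparse_seeds(outlines, k=10)
        assert len(seeds) == 1  # only the anchor survives

    def test_no_outlines(self):
        seeds = propagate_sparse_seeds(np.zeros((5, 4, 4), dtype=bool), k=10)
        assert seeds.shape == (0, 3)


class TestLesionVolume:
    def test_arithmetic(self):
        from myofiberct.fibrosis import LesionSegmentation

        mask = np.zeros((10, 10, 10), dtype=bool)
        mask.flat[:1000] = True
        seg = LesionSegmentation(mask=mask, seeds=np.zeros((1, 3), int), tolerance=1, ceiling=1)
        lv = lesion_volume(seg, voxel_size_um=100.0)
        assert lv.total_mm3 == pytest.approx(1.0)

    def test_empty(self):
        from myofiberct.fibrosis import LesionSegmentation

        seg = LesionSegmentation(mask=np.zeros((4, 4, 4), bool), seeds=np.zeros((1, 3), int),
                                 tolerance=1, ceiling=1)
        lv = lesion_volume(seg, voxel_size_um=100.0)
        assert lv.total_mm3 == 0.0 and lv.n_components == 0

    def test_component_split_conserves_volume(self):
        from myofiberct.fibrosis import LesionSegmentation

        mask = np.zeros((9, 9, 9), dtype=bool)
        mask[1:8, 1:8, 1:8] = True
        seg = LesionSegmentation(mask=mask, seeds=np.zeros((1, 3), int), tolerance=1, ceiling=1)
        whole = lesion_volume(seg, 100.0)
        erased = mask.copy()
        erased[:, 4, :] = False  # erasure plane
        seg2 = LesionSegmentation(mask=erased, seeds=np.zeros((1, 3), int), tolerance=1, ceiling=1)
        split = lesion_volume(seg2, 100.0)
        n_erased = int(mask[:, 4, :].sum())
        assert split.total_mm3 == pytest.approx(whole.total_mm3 - n_erased * 0.1**3)
        assert split.n_components == 2


def test_default_ceiling_below_median(aligned_small):
    _, vol, truth = aligned_small
    ceil = default_hypodensity_ceiling(vol.data, truth.myocardial_mask)
    assert ceil < np.median(vol.data[truth.myocardial_mask])
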