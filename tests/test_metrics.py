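"""Helical angle, FA, MDI, circumferential fraction, local frames."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from myofiberct import (
    PhantomSpec,
    build_local_frame,
    circumferential_fraction,
    fa_from_eigenvalues,
    generate_ring_phantom,
    helical_angle,
    mdi,
)
from myofiberct.metrics import MetricMap, disarray_index
from myofiberct.tensor import OrientationField


def _field_from_vectors(v3: np.ndarray, valid=None) -> OrientationField:
    """Orientation field with prescribed v3 (eigenvalues set to a generic
    anisotropic triple)."""
    shape = v3.shape[:-1]
    ev = np.zeros(shape + (3,), dtype=np.float32)
    ev[...] = (3.0, 2.0, 1.0)
    if valid is None:
        valid = np.ones(shape, dtype=bool)
    return OrientationField(eigenvalues=ev, v3=v3.astype(np.float32), valid=valid)


def _uniform_frame(shape):
    """Frame with c = +col, z = +long, t = +row at every voxel."""
    t = np.zeros(shape + (3,), dtype=np.float32)
    c = np.zeros(shape + (3,), dtype=np.float32)
    z = np.zeros(shape + (3,), dtype=np.float32)
    t[..., 1] = 1.0
    c[..., 2] = 1.0
    z[..., 0] = 1.0
    from myofiberct.metrics import LocalFrame

    return LocalFrame(transmural=t, circumferential=c, longitudinal=z,
                      valid=np.ones(shape, dtype=bool), centers={})


class TestHelicalAngle:
    @pytest.mark.parametrize(
        "v3,expected",
        [
            ((0, 0, 1), 0.0),  # along c: circumferential, 0 deg
            ((1, 0, 0), 90.0),  # along z: +90 by the tie-break
            ((1 / np.sqrt(2), 0, 1 / np.sqrt(2)), 45.0),
            ((-1 / np.sqrt(2), 0, 1 / np.sqrt(2)), -45.0),
            ((0, 1, 0), 0.0),  # purely transmural: in-plane
        ],
    )
    def test_reference_directions(self, v3, expected):
        field = _field_from_vectors(np.array(v3, dtype=float).reshape(1, 1, 1, 3))
        ha = helical_angle(field, _uniform_frame((1, 1, 1)))
        assert ha.values[0, 0, 0] == pytest.approx(expected, abs=0.1)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=50, deadline=None)
    def test_sign_flip_invariance(self, seed):
        rng = np.random.default_rng(seed)
        v = rng.standard_normal((4, 4, 4, 3))
        v /= np.linalg.norm(v, axis=-1, keepdims=True)
        frame = _uniform_frame((4, 4, 4))
        ha1 = helical_angle(_field_from_vectors(v), frame)
        ha2 = helical_angle(_field_from_vectors(-v), frame)
        np.testing.assert_allclose(ha1.values, ha2.values, atol=1e-4)
        assert np.all(ha1.values >= -90) and np.all(ha1.values <= 90)


class TestFractionalAnisotropy:
    def test_isotropic_is_zero(self):
        assert fa_from_eigenvalues(2.5, 2.5, 2.5) == 0.0

    def test_fully_anisotropic_is_one(self):
        assert fa_from_eigenvalues(1.0, 0.0, 0.0) == pytest.approx(1.0)

    def test_known_triple_against_oracle(self):
        # independent one-line evaluation of the RMS-deviation formula
        l = np.array([2.0, 1.0, 1.0])
        oracle = np.sqrt(1.5) * np.linalg.norm(l - l.mean()) / np.linalg.norm(l)
        assert oracle == pytest.approx(0.4082, abs=1e-4)
        assert fa_from_eigenvalues(2, 1, 1) == pytest.approx(oracle)

    def test_all_zero_convention(self):
        assert fa_from_eigenvalues(0.0, 0.0, 0.0) == 0.0

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=100, deadline=None)
    def test_bounds_fuzz(self, seed):
        rng = np.random.default_rng(seed)
        lam = np.sort(rng.uniform(0, 10, size=(100, 3)), axis=1)[:, ::-1]
        fa = fa_from_eigenvalues(lam[:, 0], lam[:, 1], lam[:, 2])
        assert np.all((fa >= 0) & (fa <= 1))


class TestDisarrayIndex:
    def test_collinear_is_one(self):
        v = np.zeros((15, 15, 15, 3))
        v[..., 1] = 1.0
        m = disarray_index(_field_from_vectors(v), neighborhood=15)
        assert m.values[7, 7, 7] == pytest.approx(1.0, abs=1e-6)

    def test_random_isotropic_low(self):
        rng = np.random.default_rng(0)
        vals = []
        for _ in range(20):
            v = rng.standard_normal((15**3, 3))
            vals.append(mdi(v))
        assert np.mean(vals) < 0.1

    def test_half_x_half_y(self):
        # lambda_max of the mean dyad is 0.5 -> MDI = (3*0.5 - 1)/2 = 0.25
        v = np.zeros((1000, 3))
        v[:500, 2] = 1.0
        v[500:, 1] = 1.0
        assert mdi(v) == pytest.approx(0.25, abs=1e-12)

    def test_invalid_neighbors_excluded(self):
        v = np.zeros((15, 15, 15, 3))
        v[..., 1] = 1.0
        valid = np.zeros((15, 15, 15), dtype=bool)
        valid[7, 7, 7] = True  # < 10% valid neighbors everywhere
        m = disarray_index(_field_from_vectors(v, valid), neighborhood=15)
        assert not m.valid.any()

    @pytest.mark.parametrize("bad", [2, 4, 1])
    def test_neighborhood_validation(self, bad):
        v = np.zeros((5, 5, 5, 3))
        v[..., 1] = 1.0
        with pytest.raises(ValueError):
            disarray_index(_field_from_vectors(v), neighborhood=bad)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=50, deadline=None)
    def test_bounds_fuzz(self, seed):
        rng = np.random.default_rng(seed)
        v = rng.standard_normal((50, 3))
        assert 0.0 <= mdi(v) <= 1.0


class TestLocalFrame:
    def test_annulus_geometry_and_orthonormality(self):
        spec = PhantomSpec(shape=(4, 64, 64), inner_radius=10, outer_radius=25, seed=0)
        _, truth = generate_ring_phantom(spec)
        frame = build_local_frame(truth.mask())
        m = frame.valid
        for a, b in [(frame.transmural, frame.circumferential),
                     (frame.transmural, frame.longitudinal),
                     (frame.circumferential, frame.longitudinal)]:
            dots = np.abs(np.einsum("...i,...i->...", a, b)[m])
            assert dots.max() < 1e-6
        for a in (frame.transmural, frame.circumferential, frame.longitudinal):
            norms = np.linalg.norm(a[m], axis=-1)
            np.testing.assert_allclose(norms, 1.0, atol=1e-6)
        # at angle 0 (voxel straight +col of center) t is +col, c is +row
        cy, cx = frame.centers[2]
        k = int(round(cy)), int(round(cx + 18))
        t = frame.transmural[2][k]
        c = frame.circumferential[2][k]
        assert t[2] == pytest.approx(1.0, abs=0.05)
        assert abs(c[1]) == pytest.approx(1.0, abs=0.05)

    def test_half_ring_frame_matches_full_ring(self):
        kw = dict(shape=(6, 120, 120), inner_radius=25, outer_radius=50, seed=3, noise_sigma=0)
        _, tf = generate_ring_phantom(PhantomSpec(**kw))
        _, th = generate_ring_phantom(PhantomSpec(**kw, angular_span_deg=180))
        ff = build_local_frame(tf.mask())
        fh = build_local_frame(th.mask())
        common = th.myocardial_mask & ff.valid & fh.valid
        dots = np.einsum("...i,...i->...", ff.transmural, fh.transmural)[common]
        assert dots.min() > np.cos(np.radians(2.0))

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            build_local_frame(np.zeros((3, 8, 8), dtype=bool))


class TestCircumferentialFraction:
    def test_all_circumferential(self):
        ha = MetricMap(np.zeros((4, 4, 4), dtype=np.float32), "HA", np.ones((4, 4, 4), bool))
        assert circumferential_fraction(ha) == 100.0

    def test_all_longitudinal(self):
        ha = MetricMap(np.full((4, 4, 4), 90.0, dtype=np.float32), "HA", np.ones((4, 4, 4), bool))
        assert circumferential_fraction(ha) == 0.0

    def test_linear_profile_fraction(self, aligned_small, aligned_analysis):
        """+50..-50 linear profile: |HA| < 22.5 over 45% of the wall; the
        voxel-weighted analytic fraction is also 45% (r-weighting is
        symmetric about mid-wall).  Estimator dispersion at the threshold
        gives a few points of slack."""
        assert aligned_analysis.circumferential_pct == pytest.approx(45.0, abs=7.0)

    def test_validation(self):
        ha = MetricMap(np.zeros((2, 2, 2), dtype=np.float32), "HA", np.zeros((2, 2, 2), bool))
        with pytest.raises(ValueError):
            circumferential_fraction(ha)
        ha_ok = MetricMap(np.zeros((2, 2, 2), dtype=np.float32), "HA", np.ones((2, 2, 2), bool))
        with pytest.raises(ValueError):
            circumferential_fraction(ha_ok, threshold_deg=95)
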