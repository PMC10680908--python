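"""Evaluation statistics against dense/forced oracles."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from dyncbct.autodiff import Tensor
from dyncbct.geometry import ProjectionSet, ScanGeometry, VolumeGrid, \
    build_trajectory
from dyncbct.metrics import (TrackedTrace, amsterdam_shroud_trace, com_error,
                             compare_traces, dice, feature_point_le,
                             propagate_mask, relative_error, ssim_volume,
                             track_template)


def vol_of(arr, voxel=3.0):
    return VolumeGrid(arr, voxel, -np.array(arr.shape) * voxel / 2)


class TestRelativeError:
    def test_identical_volumes_give_zero(self, rng):
        v = vol_of(rng.uniform(0, 1, (8, 8, 8)))
        assert relative_error([v], [v]) == 0.0

    def test_zero_estimate_gives_one(self, rng):
        v = vol_of(rng.uniform(0.1, 1, (8, 8, 8)))
        z = vol_of(np.zeros((8, 8, 8)))
        assert relative_error([z], [v]) == pytest.approx(1.0)

    def test_scaled_estimate_gives_epsilon(self, rng):
        v = vol_of(rng.uniform(0.1, 1, (8, 8, 8)))
        eps = 0.037
        e = vol_of((1 + eps) * v.values)
        assert relative_error([e], [v]) == pytest.approx(eps, rel=1e-9)

    def test_multi_frame_average(self, rng):
        a = vol_of(rng.uniform(0.1, 1, (6, 6, 6)))
        b = vol_of(rng.uniform(0.1, 1, (6, 6, 6)))
        re_each = [relative_error([x], [y]) for x, y in
                   [(a, b), (b, a)]]
        assert relative_error([a, b], [b, a]) == pytest.approx(np.mean(re_each))

    def test_zero_truth_rejected(self):
        z = vol_of(np.zeros((4, 4, 4)))
        with pytest.raises(ZeroDivisionError):
            relative_error([z], [z])


def reference_ssim(a, b, data_range, sigma=1.5):
    """Independent SSIM (Gaussian window, population covariance)."""
    K1, K2 = 0.01, 0.03
    C1, C2 = (K1 * data_range) ** 2, (K2 * data_range) ** 2
    mu_a = gaussian_filter(a, sigma, truncate=3.5)
    mu_b = gaussian_filter(b, sigma, truncate=3.5)
    saa = gaussian_filter(a * a, sigma, truncate=3.5) - mu_a**2
    sbb = gaussian_filter(b * b, sigma, truncate=3.5) - mu_b**2
    sab = gaussian_filter(a * b, sigma, truncate=3.5) - mu_a * mu_b
    num = (2 * mu_a * mu_b + C1) * (2 * sab + C2)
    den = (mu_a**2 + mu_b**2 + C1) * (saa + sbb + C2)
    s = num / den
    pad = 5  # crop the filter's edge effect like the reference implementation
    return s[pad:-pad, pad:-pad, pad:-pad].mean()


class TestSsim:
    def test_identical_volumes_give_one(self, rng):
        v = vol_of(rng.uniform(0, 1, (16, 16, 16)))
        assert ssim_volume(v, v) == pytest.approx(1.0)

    def test_inverted_structured_volume_scores_low(self, rng):
        base = np.zeros((24, 24, 24))
        base[6:18, 6:18, 6:18] = 1.0
        base += rng.normal(0, 0.05, base.shape)
        v = vol_of(base)
        inv = vol_of(base.max() - base)
        assert ssim_volume(inv, v) < 0.1

    def test_matches_independent_implementation(self, rng):
        a = gaussian_filter(rng.uniform(0, 1, (32, 32, 32)), 1.0)
        b = a + rng.normal(0, 0.05, a.shape)
        ours = ssim_volume(vol_of(b), vol_of(a))
        oracle = reference_ssim(b, a, a.max() - a.min())
        assert ours == pytest.approx(oracle, abs=5e-3)


class TestComError:
    def test_identical_masks_give_zero(self, rng):
        m = vol_of((rng.uniform(size=(10, 10, 10)) > 0.7).astype(float))
        d, mag = com_error(m, m)
        np.testing.assert_allclose(d, 0.0)
        assert mag == 0.0

    def test_shifted_sphere_forced_value(self):
        base = np.zeros((16, 16, 16))
        pts = np.stack(np.meshgrid(*[np.arange(16)] * 3, indexing="ij"), -1)
        base[np.linalg.norm(pts - 7, axis=-1) <= 4] = 1.0
        shifted = np.roll(base, 2, axis=2)  # 2 voxels SI, voxel 3 mm
        d, mag = com_error(vol_of(shifted), vol_of(base))
        assert mag == pytest.approx(6.0, abs=1e-9)
        np.testing.assert_allclose(d, [0.0, 0.0, 6.0], atol=1e-9)

    def test_matches_dense_centroid_oracle(self, rng):
        a = (rng.uniform(size=(12, 12, 12)) > 0.8).astype(float)
        b = (rng.uniform(size=(12, 12, 12)) > 0.8).astype(float)
        va, vb = vol_of(a), vol_of(b)
        d, _ = com_error(va, vb)
        ca = (np.argwhere(a > 0.5) * 3.0 + va.origin).mean(axis=0)
        cb = (np.argwhere(b > 0.5) * 3.0 + vb.origin).mean(axis=0)
        np.testing.assert_allclose(d, ca - cb, atol=1e-9)

    def test_empty_mask_rejected(self):
        z = vol_of(np.zeros((4, 4, 4)))
        with pytest.raises(ValueError):
            com_error(z, z)


class TestDice:
    def test_forced_values(self):
        a = np.zeros((12, 12, 12))
        a[:10, :10, :10] = 1  # 1000 voxels
        b = np.zeros((12, 12, 12))
        b[5:10, :10, :10] = 1  # 500 voxels, all shared
        assert dice(vol_of(a), vol_of(a)) == 1.0
        assert dice(vol_of(a), vol_of(1 - a)) == 0.0
        assert dice(vol_of(a), vol_of(b)) == pytest.approx(2 * 500 / 1500)

    def test_empty_masks_rejected(self):
        z = vol_of(np.zeros((4, 4, 4)))
        with pytest.raises(ValueError):
            dice(z, z)


class _ConstantShiftModel:
    """Stand-in reconstruction model with a constant rigid DVF."""

    def __init__(self, shift):
        self.shift = np.asarray(shift, dtype=float)

    def dvf_fn(self, t):
        def dvf(pts):
            return Tensor(np.broadcast_to(self.shift, pts.data.shape).copy())
        return dvf


class TestPropagateMask:
    def test_zero_dvf_identity(self, rng):
        m = vol_of((rng.uniform(size=(10, 10, 10)) > 0.7).astype(float))
        out = propagate_mask(m, _ConstantShiftModel([0, 0, 0]), 0)
        np.testing.assert_array_equal(out.values, m.values)

    def test_integer_voxel_shift_exact(self):
        base = np.zeros((16, 16, 16))
        base[6:10, 6:10, 6:10] = 1.0
        m = vol_of(base)  # voxel 3 mm
        # backward warp with dvf = +2 voxels SI samples the reference at
        # x + 6 mm: the propagated mask appears shifted by -2 voxels
        out = propagate_mask(m, _ConstantShiftModel([0, 0, 6.0]), 0)
        np.testing.assert_array_equal(out.values, np.roll(base, -2, axis=2))

    def test_small_smooth_dvf_preserves_volume(self, rng):
        base = np.zeros((20, 20, 20))
        base[6:14, 6:14, 6:14] = 1.0
        m = vol_of(base)

        class Smooth:
            def dvf_fn(self, t):
                def dvf(pts):
                    x = pts.data
                    d = 1.5 * np.sin(x / 40.0)  # |d| <= 1.5 mm, half a voxel
                    return Tensor(d)
                return dvf

        out = propagate_mask(m, Smooth(), 0)
        assert out.values.sum() == pytest.approx(base.sum(), rel=0.05)


class TestTraceMetrics:
    def test_feature_point_le_forced(self):
        a = [TrackedTrace(np.array([10.0, 12.0]))]
        b = [TrackedTrace(np.array([12.0, 12.0]))]
        assert feature_point_le(a, a) == 0.0
        assert feature_point_le(
            [TrackedTrace(np.array([10.0]))],
            [TrackedTrace(np.array([12.0]))]) == pytest.approx(2.0)

    def test_feature_point_le_matches_dense_oracle(self, rng):
        n_frames, n_pts = 20, 4
        ref = [TrackedTrace(rng.normal(size=n_frames)) for _ in range(n_pts)]
        tst = [TrackedTrace(rng.normal(size=n_frames)) for _ in range(n_pts)]
        ours = feature_point_le(ref, tst)
        dense = np.mean([np.mean([abs(ref[q].positions[p] - tst[q].positions[p])
                                  for q in range(n_pts)])
                         for p in range(n_frames)])
        assert ours == pytest.approx(dense, abs=1e-12)

    def test_compare_traces_identities(self, rng):
        x = rng.normal(size=30)
        r, err = compare_traces(TrackedTrace(x), TrackedTrace(x))
        assert r == pytest.approx(1.0)
        assert err == 0.0
        x0 = x - x.mean()
        r2, err2 = compare_traces(TrackedTrace(x0), TrackedTrace(2 * x0))
        assert r2 == pytest.approx(1.0)
        assert err2 > 0

    def test_compare_traces_matches_textbook_formulas(self, rng):
        x, y = rng.normal(size=25), rng.normal(size=25)
        r, err = compare_traces(TrackedTrace(x), TrackedTrace(y))
        rx = ((x - x.mean()) * (y - y.mean())).sum() / \
            np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
        assert r == pytest.approx(rx, abs=1e-12)
        assert err == pytest.approx(np.abs(x - y).mean(), abs=1e-12)

    def test_validity_masks_respected(self, rng):
        x = rng.normal(size=30)
        noisy = x.copy()
        noisy[5] = 1e6  # invalid frame: must be excluded
        a = TrackedTrace(x)
        b = TrackedTrace(noisy, valid=np.arange(30) != 5)
        r, err = compare_traces(a, b)
        assert err == 0.0

    def test_degenerate_traces_rejected(self):
        with pytest.raises(ValueError):
            compare_traces(TrackedTrace(np.ones(10)), TrackedTrace(np.ones(10)))
        with pytest.raises(ValueError):
            compare_traces(TrackedTrace(np.arange(2.0)),
                           TrackedTrace(np.arange(2.0)))


class TestProjectionDomainTracking:
    @staticmethod
    def _edge_scan(motion_mm, nv=48, n_frames=40):
        """Synthetic scan of a horizontal high-contrast edge moving in SI."""
        angles, ts = build_trajectory(float(n_frames), 360.0, 1.0)
        geom = ScanGeometry(1000.0, 1500.0, 32, nv, 4.0, 4.0, angles, ts)
        v = geom.pixel_coordinates()[1]
        frames = np.zeros((n_frames, 32, nv))
        for k in range(n_frames):
            edge = motion_mm[k]
            frames[k] = 2.0 / (1.0 + np.exp((v[None, :] - edge) / 2.0))
        return ProjectionSet(frames, geom)

    def test_static_scan_trace_is_flat(self):
        proj = self._edge_scan(np.zeros(40))
        trace = amsterdam_shroud_trace(proj)
        assert np.var(trace.positions) < 0.1

    def test_recovers_sinusoidal_edge_motion(self):
        motion = 20.0 * np.sin(2 * np.pi * np.arange(40) / 8.0)
        proj = self._edge_scan(motion)
        trace = amsterdam_shroud_trace(proj, sign=-1)
        r, _ = compare_traces(TrackedTrace(motion), trace)
        assert r > 0.99

    def test_baseline_shift_amplitude_recovered(self):
        motion = np.where(np.arange(40) < 20, 0.0, 12.0)
        proj = self._edge_scan(motion)
        trace = amsterdam_shroud_trace(proj, sign=-1)
        shift = trace.positions[25:].mean() - trace.positions[:15].mean()
        assert shift == pytest.approx(12.0, abs=4.0)  # within 1 detector pixel

    def test_band_outside_detector_rejected(self):
        proj = self._edge_scan(np.zeros(40))
        with pytest.raises(ValueError):
            amsterdam_shroud_trace(proj, band=(0, 500))

    def test_template_tracker_follows_blob(self):
        nv, n = 64, 30
        motion = 6.0 * np.sin(2 * np.pi * np.arange(n) / 10.0)
        frames = np.zeros((n, 48, nv))
        u = np.arange(48)
        v = np.arange(nv)
        for k in range(n):
            cv = 32 + motion[k] / 2.0  # 2 mm pitch below
            frames[k] = np.exp(-((u[:, None] - 24) ** 2 +
                                 (v[None, :] - cv) ** 2) / 18.0)
        trace = track_template(frames, (24, 32), half_size=6, search=8,
                               pitch_v=2.0)
        r, _ = compare_traces(TrackedTrace(motion), trace)
        assert r > 0.99
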