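"""Breathing scenarios and the analytic dynamic thorax phantom."""

import numpy as np
import pytest

from dyncbct.geometry import VolumeGrid
from dyncbct.phantom import (MotionScenario, Primitive, cirs_phantom,
                             default_geometry, motion_trace,
                             render_phantom_volume, simulate_scan,
                             thorax_phantom)


@pytest.fixture
def grid():
    return VolumeGrid.empty((48, 48, 24), 8.0, center=(0, 0, -40))


class TestMotionTrace:
    def test_static_mode_is_zero(self):
        scen = MotionScenario.preset("static")
        t = np.linspace(0, 60, 200)
        np.testing.assert_allclose(motion_trace(scen, t), 0.0)

    def test_x1_amplitude_and_period(self):
        scen = MotionScenario.preset("X1", seed=3)
        t = np.linspace(0, 60, 6000)
        si = motion_trace(scen, t)[:, 2]
        # average per-cycle SI range ~ 13 mm with small cycle-to-cycle variation
        cycle = (t // 5.0).astype(int)
        ranges = [np.ptp(si[cycle == c]) for c in range(12)]
        assert np.mean(ranges) == pytest.approx(13.0, rel=0.1)
        # dominant period ~ 5 s: count end-inhale troughs
        troughs = np.sum((si[1:-1] < si[:-2]) & (si[1:-1] < si[2:])
                         & (si[1:-1] < -0.5 * np.abs(si).max()))
        assert troughs == pytest.approx(12, abs=1)

    def test_x2_baseline_shift(self):
        scen = MotionScenario.preset("X2", seed=3)
        base_only_start = motion_trace(scen, 0.0)
        # compare end-exhale baselines before and after the transition: sample
        # at exhale times (cos^4 ~ 0) near t=15 s and t=55 s
        t = np.linspace(0, 60, 6000)
        si = motion_trace(scen, t)[:, 2]
        early = si[(t > 5) & (t < 25)].max()
        late = si[(t > 35) & (t < 60)].max()
        assert late - early == pytest.approx(5.0, abs=0.5)

    def test_deterministic_given_seed(self):
        scen = MotionScenario.preset("X3", seed=9)
        t = np.linspace(0, 60, 100)
        np.testing.assert_array_equal(motion_trace(scen, t),
                                      motion_trace(scen, t))

    def test_x4_period_drift_increases_cycle_length(self):
        scen = MotionScenario.preset("X4", seed=1)
        t = np.linspace(0, 60, 12000)
        si = motion_trace(scen, t)[:, 2]
        peaks = t[1:-1][(si[1:-1] < si[:-2]) & (si[1:-1] < si[2:])
                        & (si[1:-1] < -0.4 * np.abs(si).max())]
        # de-duplicate numerical double-detections on the flat trough
        peaks = peaks[np.insert(np.diff(peaks) > 1.0, 0, True)]
        gaps = np.diff(peaks)
        assert gaps[-1] > gaps[0]  # breathing slows down

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            MotionScenario.preset("X9")


class TestRenderPhantom:
    def test_deterministic(self, grid):
        spec = thorax_phantom()
        v1, m1, c1 = render_phantom_volume(spec, np.zeros(3), grid)
        v2, m2, c2 = render_phantom_volume(spec, np.zeros(3), grid)
        np.testing.assert_array_equal(v1.values, v2.values)
        np.testing.assert_array_equal(m1, m2)

    def test_mask_centroid_matches_analytic_com(self, grid):
        spec = thorax_phantom()
        disp = np.array([0.0, 1.5, -6.0])
        vol, mask, com = render_phantom_volume(spec, disp, grid)
        centroid = grid.origin + np.argwhere(mask).mean(axis=0) * grid.voxel_size
        assert np.all(np.abs(centroid - com) <= grid.voxel_size / 2)
        np.testing.assert_allclose(com, np.array(spec.tumor().center) + disp)

    def test_only_moving_primitives_change(self, grid):
        spec = thorax_phantom()
        v0, m0, _ = render_phantom_volume(spec, np.zeros(3), grid,
                                          edge_sigma_voxel=0.0)
        disp = np.array([0.0, 0.0, -10.0])
        v1, m1, _ = render_phantom_volume(spec, disp, grid,
                                          edge_sigma_voxel=0.0)
        changed = v0.values != v1.values
        # every changed voxel lies in a moving primitive's footprint at one
        # of the two displacements
        pts = grid.voxel_centers().reshape(*grid.dims, 3)
        moving = np.zeros(grid.dims, dtype=bool)
        for p in spec.primitives:
            if p.motion_scale > 0:
                moving |= p.mask(pts, np.zeros(3)) | p.mask(pts, disp)
        assert not np.any(changed & ~moving)

    def test_tumor_inside_lung_at_rest(self, grid):
        spec = thorax_phantom()
        pts = grid.voxel_centers().reshape(*grid.dims, 3)
        tumor = spec.tumor().mask(pts, np.zeros(3))
        lung = next(p for p in spec.primitives if p.name == "lung_r")
        assert np.all(lung.mask(pts, np.zeros(3))[tumor])


class TestSimulateScan:
    def test_frame_count_and_shapes(self, grid):
        geom = default_geometry(n_frames=12, duration_s=12.0,
                                det_shape=(32, 24), det_pitch=16.0)
        proj, truth = simulate_scan(thorax_phantom(),
                                    MotionScenario.preset("X1"), geom, grid,
                                    seed=4)
        assert proj.frames.shape == (12, 32, 24)
        assert truth.displacements.shape == (12, 3)
        np.testing.assert_allclose(
            truth.com_trajectory,
            np.asarray(thorax_phantom().tumor().center) + truth.displacements)

    def test_reproducible_from_seed(self, grid):
        geom = default_geometry(n_frames=4, duration_s=4.0, det_shape=(16, 12),
                                det_pitch=32.0)
        spec = thorax_phantom()
        scen = MotionScenario.preset("X1")
        p1, _ = simulate_scan(spec, scen, geom, grid, seed=5, noise_sigma=0.01)
        p2, _ = simulate_scan(spec, scen, geom, grid, seed=5, noise_sigma=0.01)
        np.testing.assert_array_equal(p1.frames, p2.frames)

    def test_static_scenario_consistent_with_phantom(self, grid):
        geom = default_geometry(n_frames=8, duration_s=8.0, det_shape=(24, 16),
                                det_pitch=24.0)
        spec = thorax_phantom()
        proj, truth = simulate_scan(spec, MotionScenario.preset("static"),
                                    geom, grid, seed=0)
        # static: every frame projects the same volume
        v0 = truth.volume_at(0).values
        v5 = truth.volume_at(5).values
        np.testing.assert_array_equal(v0, v5)

    def test_half_fan_tumor_visibility_band(self):
        """Off-axis tumor leaves the field of view over a contiguous angular
        band under a half-fan geometry."""
        grid = VolumeGrid.empty((48, 48, 16), 7.0)
        geom = default_geometry(n_frames=72, duration_s=60.0,
                                det_shape=(40, 16), det_pitch=6.0,
                                det_offset_u=90.0, fan_mode="half")
        spec = cirs_phantom(tumor_center=(-80.0, 0.0, 0.0))
        proj, truth = simulate_scan(spec, MotionScenario.preset("static"),
                                    geom, grid, seed=0)
        vis = np.array([truth.tumor_visible(k) for k in range(72)])
        assert vis.any() and (~vis).any()
        # invisibility forms one contiguous band (circular)
        flips = np.sum(vis != np.roll(vis, 1))
        assert flips == 2
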