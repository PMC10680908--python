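"""Analytic dynamic thorax phantom and scripted breathing scenarios.

The phantom is a set of labeled geometric primitives (body ellipsoid, two
lung ellipsoids, a spine cylinder, hemispherical diaphragm domes and a
spherical lung tumor) with realistic attenuation values.  Breathing is an
end-exhale-weighted cos^4 waveform whose amplitude, period and baseline can
vary cycle-to-cycle, reproducing the standard classes of respiratory
irregularity: amplitude variation, rapid baseline shift, period drift, and a
single-cycle (slow breathing) scan.  The tumor and the diaphragm domes
follow the breathing trace rigidly while the chest wall and spine stay
static, so the overall field the reconstruction must recover is non-rigid.

All randomness (cycle-by-cycle modulation, projection noise) is drawn from
an explicit seed, and the analytic tumor center of mass is bookkept exactly:
``COM(t) = COM_static + trace(t)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import ProjectionSet, ScanGeometry, VolumeGrid, build_trajectory
from .projector import forward_project_grid

__all__ = ["Primitive", "PhantomSpec", "MotionScenario", "motion_trace",
           "render_phantom_volume", "simulate_scan", "thorax_phantom",
           "cirs_phantom", "ScanTruth", "default_geometry"]

# attenuation (mm^-1) at CBCT energies, approximate soft-tissue/lung/bone
MU_SOFT = 0.02
MU_LUNG = 0.004
MU_BONE = 0.035


@dataclass
class Primitive:
    """One labeled geometric body; later primitives paint over earlier ones.

    ``kind``: ellipsoid | sphere | cylinder_z | hemisphere_up.
    ``size``: semi-axes (ellipsoid), radius (others); hemisphere_up is the
    upper half (z >= center_z) of a sphere.  ``motion_scale`` in [0, 1] links
    the primitive to the breathing trace (1 = full displacement).
    """

    name: str
    kind: str
    center: tuple[float, float, float]
    size: tuple[float, ...]
    mu: float
    motion_scale: float = 0.0

    def mask(self, pts: np.ndarray, displacement: np.ndarray) -> np.ndarray:
        c = np.asarray(self.center) + self.motion_scale * displacement
        r = pts - c
        if self.kind == "ellipsoid":
            s = np.asarray(self.size)
            return (r / s).__pow__(2).sum(axis=-1) <= 1.0
        if self.kind == "sphere":
            return (r**2).sum(axis=-1) <= self.size[0] ** 2
        if self.kind == "cylinder_z":
            return (r[..., 0] ** 2 + r[..., 1] ** 2 <= self.size[0] ** 2) \
                & (np.abs(r[..., 2]) <= self.size[1])
        if self.kind == "hemisphere_up":
            return ((r**2).sum(axis=-1) <= self.size[0] ** 2) & (r[..., 2] >= 0)
        raise ValueError(f"unknown primitive kind {self.kind!r}")


@dataclass
class PhantomSpec:
    """The phantom: an ordered list of primitives (paint order matters)."""

    primitives: list[Primitive]

    def __post_init__(self):
        if not self.primitives:
            raise ValueError("phantom needs at least one primitive")
        if any(p.mu < 0 for p in self.primitives):
            raise ValueError("attenuations must be nonnegative")

    def tumor(self) -> Primitive:
        for p in self.primitives:
            if p.name == "tumor":
                return p
        raise ValueError("phantom has no tumor primitive")


def thorax_phantom(tumor_diameter_mm: float = 30.0) -> PhantomSpec:
    """Thorax analog: body, lungs, spine, diaphragm domes, lower-lobe tumor.

    The tumor sits at the isocenter (z = 0), the usual clinical setup, so the
    moving anatomy is well inside the projection field of view.
    """
    domes = [
        Primitive("diaphragm_r", "hemisphere_up", (70.0, 0.0, -90.0), (60.0,),
                  MU_SOFT, motion_scale=1.0),
        Primitive("diaphragm_l", "hemisphere_up", (-70.0, 0.0, -90.0), (60.0,),
                  MU_SOFT, motion_scale=1.0),
    ]
    return PhantomSpec([
        Primitive("body", "ellipsoid", (0.0, 0.0, 60.0), (160.0, 110.0, 220.0),
                  MU_SOFT),
        Primitive("lung_r", "ellipsoid", (70.0, 0.0, 50.0), (60.0, 75.0, 140.0),
                  MU_LUNG),
        Primitive("lung_l", "ellipsoid", (-70.0, 0.0, 50.0), (60.0, 75.0, 140.0),
                  MU_LUNG),
        *domes,
        Primitive("spine", "cylinder_z", (0.0, 85.0, 60.0), (18.0, 200.0),
                  MU_BONE),
        Primitive("tumor", "sphere", (70.0, 0.0, 0.0),
                  (tumor_diameter_mm / 2.0,), MU_SOFT, motion_scale=1.0),
    ])


def cirs_phantom(tumor_diameter_mm: float = 30.0,
                 tumor_center=(-60.0, 0.0, 0.0)) -> PhantomSpec:
    """Dynamic thorax phantom analog: static body/lungs, one moving tumor.

    The tumor sits off-axis in the left lung, so a half-fan scan loses it
    from the field of view over a contiguous angular band.
    """
    return PhantomSpec([
        Primitive("body", "ellipsoid", (0.0, 0.0, 0.0), (150.0, 100.0, 120.0),
                  MU_SOFT),
        Primitive("lung_r", "ellipsoid", (65.0, 0.0, 0.0), (55.0, 65.0, 110.0),
                  MU_LUNG),
        Primitive("lung_l", "ellipsoid", (-65.0, 0.0, 0.0), (55.0, 65.0, 110.0),
                  MU_LUNG),
        Primitive("tumor", "sphere", tumor_center, (tumor_diameter_mm / 2.0,),
                  MU_SOFT, motion_scale=1.0),
    ])


@dataclass
class MotionScenario:
    """Parametrized breathing trace.

    SI displacement is ``baseline(t) - A(t) * cos^4(pi * phase(t))`` with
    per-cycle amplitude multipliers, an optional smooth baseline shift, and
    an optional linear period drift; AP displacement is a fixed fraction of
    SI, LR is zero.  ``mode`` tags the named scenario presets.
    """

    mode: str = "X1"
    base_period_s: float = 5.0
    amplitude_si_mm: float = 13.0        # peak-to-peak SI range
    ap_ratio: float = 0.3                # AP amplitude as a fraction of SI
    amplitude_modulation: float = 0.05   # s.d. of per-cycle multipliers
    baseline_shift_mm: float = 0.0
    baseline_onset_s: float = 30.0
    baseline_transition_s: float = 2.0
    period_drift_per_cycle: float = 0.0  # fractional period change per cycle
    amplitude_drift_total: float = 0.0   # fractional amplitude ramp over scan
    duration_s: float = 60.0
    seed: int = 0

    def __post_init__(self):
        if self.base_period_s <= 0:
            raise ValueError("period must be positive")
        if self.amplitude_si_mm < 0:
            raise ValueError("amplitude must be nonnegative")

    @classmethod
    def preset(cls, mode: str, seed: int = 0, duration_s: float = 60.0,
               amplitude_si_mm: float = 13.0) -> "MotionScenario":
        """Named scenario analogs; amplitude/duration are configurable."""
        base = dict(seed=seed, duration_s=duration_s,
                    amplitude_si_mm=amplitude_si_mm, mode=mode)
        presets = {
            "static": dict(amplitude_si_mm=0.0, amplitude_modulation=0.0),
            "X1": dict(),
            "X2": dict(baseline_shift_mm=5.0),
            "X3": dict(amplitude_modulation=0.15, baseline_shift_mm=5.0),
            "X4": dict(period_drift_per_cycle=0.04, amplitude_drift_total=0.4),
            "X5": dict(base_period_s=duration_s, amplitude_modulation=0.0),
            "X6": dict(amplitude_modulation=0.15, baseline_shift_mm=5.0,
                       period_drift_per_cycle=0.04),
            "irregular": dict(amplitude_modulation=0.25,
                              period_drift_per_cycle=0.0),
        }
        if mode not in presets:
            raise ValueError(f"unknown scenario mode {mode!r}")
        over = presets[mode]
        if mode == "static":
            base.pop("amplitude_si_mm")
        return cls(**{**base, **over})


def _cycle_multipliers(scenario: MotionScenario, n_cycles: int) -> np.ndarray:
    rng = np.random.default_rng(scenario.seed)
    m = rng.normal(1.0, scenario.amplitude_modulation, n_cycles)
    return np.clip(m, 0.3, 1.7)


def motion_trace(scenario: MotionScenario, t) -> np.ndarray:
    """Displacement (LR, AP, SI) in mm at time(s) t; deterministic in the seed.

    Positive SI baseline is superior; the cos^4 excursion is inferior
    (diaphragm and tumor move caudally on inhale).
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    if scenario.mode == "static":
        out = np.zeros((t.size, 3))
        return out if out.shape[0] > 1 else out[0]
    # phase in cycles under a linear period drift
    T0 = scenario.base_period_s
    drift = scenario.period_drift_per_cycle
    if drift == 0:
        phase = t / T0
    else:
        # period T(n) = T0 * (1 + drift)^n; invert cumulative time analytically
        # sum_{0..n} T0 (1+d)^k = T0 ((1+d)^{n+1} - 1)/d = t  ->  n(t)
        phase = np.log1p(drift * t / T0) / np.log1p(drift)
    cyc = np.floor(phase).astype(int)
    mods = _cycle_multipliers(scenario, int(cyc.max()) + 1)
    amp = scenario.amplitude_si_mm * mods[cyc]
    if scenario.amplitude_drift_total:
        amp = amp * (1.0 + scenario.amplitude_drift_total * t / scenario.duration_s)
    si = -amp * np.cos(np.pi * phase) ** 4
    if scenario.baseline_shift_mm:
        s = (t - scenario.baseline_onset_s) / max(scenario.baseline_transition_s, 1e-6)
        si = si + scenario.baseline_shift_mm / (1.0 + np.exp(-4.0 * s))
    ap = scenario.ap_ratio * si
    out = np.stack([np.zeros_like(si), ap, si], axis=-1)
    return out if out.shape[0] > 1 else out[0]


def render_phantom_volume(spec: PhantomSpec, displacement, grid: VolumeGrid,
                          edge_sigma_voxel: float = 0.7
                          ) -> tuple[VolumeGrid, np.ndarray, np.ndarray]:
    """Rasterize the displaced phantom.

    Returns (attenuation volume, binary tumor mask, analytic tumor COM mm).
    Moving primitives are offset by ``motion_scale * displacement``.
    ``edge_sigma_voxel`` applies a Gaussian edge profile (in voxels) to the
    attenuation map, emulating partial-volume / finite-focal-spot blur;
    0 gives hard binary edges.  The tumor mask is always computed from the
    exact geometry.
    """
    from scipy.ndimage import gaussian_filter

    displacement = np.asarray(displacement, dtype=float)
    pts = grid.voxel_centers().reshape(*grid.dims, 3)
    vals = np.zeros(grid.dims)
    tumor_mask = np.zeros(grid.dims, dtype=bool)
    for p in spec.primitives:
        m = p.mask(pts, displacement)
        vals[m] = p.mu
        if p.name == "tumor":
            tumor_mask = m
    if edge_sigma_voxel > 0:
        vals = gaussian_filter(vals, edge_sigma_voxel)
    tumor = spec.tumor()
    com = np.asarray(tumor.center) + tumor.motion_scale * displacement
    return grid.like(vals), tumor_mask, com


def default_geometry(n_frames: int = 660, duration_s: float = 60.0,
                     arc_deg: float = 360.0, det_shape=(256, 192),
                     det_pitch: float = 1.6, sad: float = 1000.0,
                     sdd: float = 1500.0, det_offset_u: float = 0.0,
                     fan_mode: str = "full") -> ScanGeometry:
    """A clinical-style scan geometry (1-min, 360 deg, 11 fps by default)."""
    fps = n_frames / duration_s
    angles, ts = build_trajectory(duration_s, arc_deg, fps)
    return ScanGeometry(sad, sdd, det_shape[0], det_shape[1], det_pitch,
                        det_pitch, angles, ts, det_offset_u=det_offset_u,
                        fan_mode=fan_mode)


@dataclass
class ScanTruth:
    """Ground truth of a simulated scan, rendered lazily per frame."""

    spec: PhantomSpec
    scenario: MotionScenario
    grid: VolumeGrid
    displacements: np.ndarray      # (n_frames, 3) mm
    com_trajectory: np.ndarray     # (n_frames, 3) mm
    geometry: ScanGeometry

    def volume_at(self, frame: int) -> VolumeGrid:
        vol, _, _ = render_phantom_volume(self.spec, self.displacements[frame],
                                          self.grid)
        return vol

    def tumor_mask_at(self, frame: int) -> np.ndarray:
        _, mask, _ = render_phantom_volume(self.spec, self.displacements[frame],
                                           self.grid)
        return mask

    def tumor_visible(self, frame: int) -> bool:
        """Whether the tumor COM projects inside the detector for the frame."""
        g = self.geometry
        src = g.source_position(frame)
        center, u_axis, v_axis = g.detector_axes(frame)
        n = (center - src)
        n = n / np.linalg.norm(n)
        ray = self.com_trajectory[frame] - src
        scale = np.dot(center - src, n) / np.dot(ray, n)
        hit = src + scale * ray
        u = np.dot(hit - center, u_axis)
        v = np.dot(hit - center, v_axis)
        uu, vv = g.pixel_coordinates()
        return bool(uu[0] <= u <= uu[-1] and vv[0] <= v <= vv[-1])


def simulate_scan(spec: PhantomSpec, scenario: MotionScenario,
                  geometry: ScanGeometry, grid: VolumeGrid, seed: int = 0,
                  noise_sigma: float = 0.0) -> tuple[ProjectionSet, ScanTruth]:
    """Render the displaced phantom per frame and project it at each angle.

    Optional zero-mean Gaussian noise (s.d. in line-integral units) is added
    to the projections.  Fully reproducible given the seed.
    """
    scenario = replace(scenario, seed=seed)
    times = geometry.timestamps
    disps = motion_trace(scenario, times)
    if disps.ndim == 1:
        disps = disps[None, :]
    tumor = spec.tumor()
    com = np.asarray(tumor.center) + tumor.motion_scale * disps
    frames = np.empty((geometry.n_frames, geometry.det_nu, geometry.det_nv))
    for k in range(geometry.n_frames):
        vol, _, _ = render_phantom_volume(spec, disps[k], grid)
        frames[k] = forward_project_grid(vol, geometry, k)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed + 7)
        frames += rng.normal(0.0, noise_sigma, frames.shape)
    projections = ProjectionSet(frames, geometry)
    truth = ScanTruth(spec, scenario, grid, disps, com, geometry)
    return projections, truth
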