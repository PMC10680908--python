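"""Cone-beam scan geometry, projection containers and volume grids.

Conventions
-----------
World coordinates are in mm with the isocenter at the origin.  Gantry angles
are in degrees, counterclockwise about the +z (superior-inferior) axis, with
the source on the +y axis at 0 degrees.  Volume arrays are indexed (x, y, z)
with voxel centers at ``origin + index * voxel_size``.  Axis meaning follows
radiotherapy usage: x = left-right (LR), y = anterior-posterior (AP),
z = superior-inferior (SI).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ScanGeometry",
    "ProjectionSet",
    "VolumeGrid",
    "build_trajectory",
    "intensity_to_line_integral",
]


@dataclass
class ScanGeometry:
    """Circular cone-beam acquisition geometry.

    Parameters
    ----------
    sad, sdd : float
        Source-to-axis and source-to-detector distances, mm (``sdd > sad > 0``).
    det_nu, det_nv : int
        Detector pixel counts, lateral (u) and axial (v).
    det_pitch_u, det_pitch_v : float
        Detector pixel size, mm.
    angles, timestamps : ndarray
        Per-frame gantry angles (deg) and acquisition times (s).
    det_offset_u : float
        Lateral detector offset, mm; 0 for full-fan, nonzero for half-fan.
    fan_mode : {"full", "half"}
    """

    sad: float
    sdd: float
    det_nu: int
    det_nv: int
    det_pitch_u: float
    det_pitch_v: float
    angles: np.ndarray
    timestamps: np.ndarray
    det_offset_u: float = 0.0
    fan_mode: str = "full"

    def __post_init__(self):
        self.angles = np.asarray(self.angles, dtype=float)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if not (self.sdd > self.sad > 0):
            raise ValueError(f"require sdd > sad > 0, got sad={self.sad}, sdd={self.sdd}")
        if self.det_pitch_u <= 0 or self.det_pitch_v <= 0:
            raise ValueError("detector pitch must be positive")
        if self.angles.shape != self.timestamps.shape:
            raise ValueError("angles and timestamps must have equal length")
        if self.angles.size >= 2 and not np.all(np.diff(self.timestamps) > 0):
            raise ValueError("timestamps must be strictly increasing")
        if self.fan_mode not in ("full", "half"):
            raise ValueError(f"unknown fan_mode {self.fan_mode!r}")

    @property
    def n_frames(self) -> int:
        return int(self.angles.size)

    @property
    def magnification(self) -> float:
        return self.sdd / self.sad

    # -- per-frame ray geometry -------------------------------------------
    def source_position(self, frame: int) -> np.ndarray:
        th = np.deg2rad(self.angles[frame])
        return np.array([-self.sad * np.sin(th), self.sad * np.cos(th), 0.0])

    def detector_axes(self, frame: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (center, u_axis, v_axis) of the detector plane in mm."""
        th = np.deg2rad(self.angles[frame])
        direction = np.array([np.sin(th), -np.cos(th), 0.0])  # source -> detector
        center = direction * (self.sdd - self.sad)
        u_axis = np.array([np.cos(th), np.sin(th), 0.0])
        v_axis = np.array([0.0, 0.0, 1.0])
        return center, u_axis, v_axis

    def pixel_coordinates(self) -> tuple[np.ndarray, np.ndarray]:
        """Detector-plane (u, v) coordinates of pixel centers, mm."""
        u = (np.arange(self.det_nu) - (self.det_nu - 1) / 2.0) * self.det_pitch_u \
            + self.det_offset_u
        v = (np.arange(self.det_nv) - (self.det_nv - 1) / 2.0) * self.det_pitch_v
        return u, v

    def rays(self, frame: int, pixel_idx: np.ndarray | None = None
             ) -> tuple[np.ndarray, np.ndarray]:
        """Ray origins and unit directions for detector pixels of one frame.

        ``pixel_idx`` is an optional flat index array into the (nu, nv)
        C-ordered pixel grid; by default all pixels are returned.
        Returns arrays of shape (n_rays, 3).
        """
        if not (0 <= frame < self.n_frames):
            raise IndexError(f"frame {frame} out of range [0, {self.n_frames})")
        u, v = self.pixel_coordinates()
        uu, vv = np.meshgrid(u, v, indexing="ij")
        uu, vv = uu.ravel(), vv.ravel()
        if pixel_idx is not None:
            uu, vv = uu[pixel_idx], vv[pixel_idx]
        center, u_axis, v_axis = self.detector_axes(frame)
        pix = center + uu[:, None] * u_axis + vv[:, None] * v_axis
        src = self.source_position(frame)
        d = pix - src
        d /= np.linalg.norm(d, axis=1, keepdims=True)
        return np.broadcast_to(src, d.shape).copy(), d

    @property
    def fan_angle_deg(self) -> float:
        """Full fan opening angle subtended by the detector at the source."""
        u, _ = self.pixel_coordinates()
        half = max(abs(u[0]), abs(u[-1])) + self.det_pitch_u / 2.0
        return float(2.0 * np.rad2deg(np.arctan2(half, self.sdd)))


@dataclass
class ProjectionSet:
    """An ordered stack of line-integral projection frames.

    ``frames`` has shape (n_frames, det_nu, det_nv); values are dimensionless
    line integrals of the attenuation (mm^-1 integrated over mm).
    """

    frames: np.ndarray
    geometry: ScanGeometry

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a 3D (n_frames, nu, nv) stack")
        n, nu, nv = self.frames.shape
        g = self.geometry
        if n != g.n_frames or nu != g.det_nu or nv != g.det_nv:
            raise ValueError(
                f"projection stack shape {self.frames.shape} does not match geometry "
                f"({g.n_frames}, {g.det_nu}, {g.det_nv})")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("projection frames contain non-finite values")

    @property
    def frame_count(self) -> int:
        return self.frames.shape[0]


@dataclass
class VolumeGrid:
    """A sampled attenuation volume (mm^-1) on a regular grid."""

    values: np.ndarray
    voxel_size: np.ndarray
    origin: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.voxel_size = np.broadcast_to(np.asarray(self.voxel_size, dtype=float), (3,)).copy()
        self.origin = np.asarray(self.origin, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("volume values must be 3D")
        if np.any(self.voxel_size <= 0):
            raise ValueError("voxel size must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume contains non-finite values")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.values.shape

    @classmethod
    def empty(cls, dims, voxel_size, center=(0.0, 0.0, 0.0)) -> "VolumeGrid":
        """An all-zero grid of ``dims`` voxels centered at ``center`` (mm)."""
        dims = tuple(int(d) for d in dims)
        vs = np.broadcast_to(np.asarray(voxel_size, dtype=float), (3,))
        origin = np.asarray(center, dtype=float) - (np.array(dims) - 1) / 2.0 * vs
        return cls(np.zeros(dims), vs, origin)

    def like(self, values: np.ndarray) -> "VolumeGrid":
        return VolumeGrid(values, self.voxel_size.copy(), self.origin.copy())

    def axis_coords(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return tuple(self.origin[k] + np.arange(self.dims[k]) * self.voxel_size[k]
                     for k in range(3))

    def voxel_centers(self) -> np.ndarray:
        """World coordinates of all voxel centers, shape (nx*ny*nz, 3), C order."""
        cx, cy, cz = self.axis_coords()
        g = np.meshgrid(cx, cy, cz, indexing="ij")
        return np.stack([a.ravel() for a in g], axis=-1)

    def world_to_index(self, points_mm: np.ndarray) -> np.ndarray:
        return (np.asarray(points_mm) - self.origin) / self.voxel_size

    @property
    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        """(lo, hi) mm corners of the voxel-center bounding box."""
        hi = self.origin + (np.array(self.dims) - 1) * self.voxel_size
        return self.origin.copy(), hi

    def center(self) -> np.ndarray:
        lo, hi = self.bounding_box
        return (lo + hi) / 2.0


def build_trajectory(duration_s: float, arc_deg: float, fps: float,
                     start_deg: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """Uniform circular trajectory: angles (deg) and timestamps (s).

    ``n = round(duration_s * fps)`` frames uniformly spaced over
    ``[start_deg, start_deg + arc_deg)``; frame k is acquired at ``k / fps``.
    A negative arc gives a clockwise scan.
    """
    if duration_s <= 0 or fps <= 0:
        raise ValueError("duration_s and fps must be positive")
    if arc_deg == 0:
        raise ValueError("arc_deg must be nonzero")
    n = int(round(duration_s * fps))
    k = np.arange(n)
    angles = start_deg + k * (arc_deg / n)
    timestamps = k / fps
    return angles, timestamps


def intensity_to_line_integral(intensity: np.ndarray, i0: float) -> np.ndarray:
    """Convert raw detector intensities to line integrals via -log(I / I0)."""
    if i0 <= 0:
        raise ValueError("I0 must be positive")
    return -np.log(np.clip(np.asarray(intensity, dtype=float), 1e-12, None) / i0)
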