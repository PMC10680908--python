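"""Forward projection: line integrals of grid volumes and continuous fields.

Both projectors march rays from the source through each requested detector
pixel with a fixed step (Joseph-style sampling, trapezoid weights).  The grid
projector samples a voxel array by trilinear interpolation and is purely
numerical; the field projector evaluates an arbitrary continuous attenuation
field (optionally warped by a deformation vector field) through the autodiff
tape, so the rendered radiograph is differentiable with respect to field and
motion parameters.
"""

from __future__ import annotations

from typing import Callable

import numpy as np
from scipy.ndimage import map_coordinates

from .autodiff import Tensor, as_tensor
from .geometry import ProjectionSet, ScanGeometry, VolumeGrid

__all__ = ["forward_project_grid", "forward_project_field", "ray_box_range",
           "simulate_projections"]


def ray_box_range(origins: np.ndarray, directions: np.ndarray,
                  box_lo: np.ndarray, box_hi: np.ndarray
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Entry/exit parameters of rays ``o + t d`` with an axis-aligned box.

    Rays that miss the box get ``t_max <= t_min``.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = 1.0 / directions
        t0 = (box_lo - origins) * inv
        t1 = (box_hi - origins) * inv
    # where a direction component is 0, the ray is parallel to those faces
    parallel = directions == 0
    inside = (origins >= box_lo) & (origins <= box_hi)
    t0 = np.where(parallel, np.where(inside, -np.inf, np.inf), t0)
    t1 = np.where(parallel, np.where(inside, np.inf, -np.inf), t1)
    tmin = np.maximum.reduce(np.minimum(t0, t1), axis=-1)
    tmax = np.minimum.reduce(np.maximum(t0, t1), axis=-1)
    tmin = np.maximum(tmin, 0.0)
    return tmin, np.maximum(tmax, tmin)


def _sample_points(geometry: ScanGeometry, frame: int, box_lo, box_hi,
                   step: float, pixel_idx=None):
    """Ray sample positions (n_rays, n_samples, 3) and trapezoid weights."""
    origins, directions = geometry.rays(frame, pixel_idx)
    tmin, tmax = ray_box_range(origins, directions, box_lo, box_hi)
    span = tmax - tmin
    # sample count from the box diagonal, not the batch: the discretized
    # operator must be identical for any ray subset
    diag = float(np.linalg.norm(np.asarray(box_hi) - np.asarray(box_lo)))
    n_samples = max(int(np.ceil(diag / step)) + 1, 2)
    # per-ray uniform sampling between entry and exit, shared sample count
    ts = tmin[:, None] + span[:, None] * np.linspace(0.0, 1.0, n_samples)[None, :]
    pts = origins[:, None, :] + ts[..., None] * directions[:, None, :]
    dt = span / (n_samples - 1)
    w = np.ones(n_samples)
    w[0] = w[-1] = 0.5
    weights = dt[:, None] * w[None, :]
    return pts, weights


def forward_project_grid(volume: VolumeGrid, geometry: ScanGeometry,
                         frame_index: int, step: float | None = None,
                         pixel_idx: np.ndarray | None = None) -> np.ndarray:
    """Line integrals of a grid volume along source-to-pixel rays.

    Returns a (det_nu, det_nv) image, or a flat array if ``pixel_idx`` is
    given.  Rays missing the volume give 0.  ``step`` defaults to half the
    smallest voxel size.
    """
    if step is None:
        step = 0.5 * float(volume.voxel_size.min())
    if step <= 0:
        raise ValueError("step must be positive")
    lo, hi = volume.bounding_box
    pts, weights = _sample_points(geometry, frame_index, lo - volume.voxel_size / 2,
                                  hi + volume.voxel_size / 2, step, pixel_idx)
    idx = (pts - volume.origin) / volume.voxel_size  # fractional voxel indices
    vals = map_coordinates(volume.values, idx.reshape(-1, 3).T, order=1,
                           mode="constant", cval=0.0).reshape(idx.shape[:2])
    proj = (vals * weights).sum(axis=1)
    if pixel_idx is None:
        return proj.reshape(geometry.det_nu, geometry.det_nv)
    return proj


def forward_project_field(attenuation_field: Callable[[Tensor], Tensor],
                          geometry: ScanGeometry, frame_index: int,
                          box_lo: np.ndarray, box_hi: np.ndarray,
                          step: float,
                          dvf: Callable[[Tensor], Tensor] | None = None,
                          ray_subset: np.ndarray | None = None) -> Tensor:
    """Differentiable line integrals of a continuous attenuation field.

    Parameters
    ----------
    attenuation_field : callable
        Maps a Tensor of mm points (M, 3) to attenuation values (M,).
    dvf : callable, optional
        Maps mm points (M, 3) to mm displacements (M, 3); the integrand is
        then ``field(x + dvf(x))`` (backward-warp convention).
    ray_subset : ndarray, optional
        Flat indices into the C-ordered (nu, nv) pixel grid.

    Returns a Tensor of per-pixel line integrals, flat over the requested rays.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    pts, weights = _sample_points(geometry, frame_index, np.asarray(box_lo),
                                  np.asarray(box_hi), step, ray_subset)
    n_rays, n_samples, _ = pts.shape
    flat = as_tensor(pts.reshape(-1, 3))
    if dvf is not None:
        flat = flat + dvf(flat)
    vals = attenuation_field(flat)
    return (vals.reshape(n_rays, n_samples) * weights).sum(axis=1)


def forward_project_voxels(volume_values: Tensor, grid_spec: VolumeGrid,
                           geometry: ScanGeometry, frame_index: int,
                           step: float | None = None,
                           ray_subset: np.ndarray | None = None) -> Tensor:
    """Differentiable-in-volume line integrals of a voxel array.

    Numerically identical to ``forward_project_grid`` on the same values,
    but ``volume_values`` may be an autodiff Tensor (e.g. the reference
    field sampled, possibly warped, at voxel centers): gradients flow back
    to the voxel values and onward to whatever produced them.  This is the
    projection operator used by the training losses, and it is the same
    operator the simulator uses to produce measurements, so rendered and
    measured radiographs share one discretization.
    """
    from . import _kernels

    if step is None:
        step = 0.5 * float(grid_spec.voxel_size.min())
    if step <= 0:
        raise ValueError("step must be positive")
    lo, hi = grid_spec.bounding_box
    pts, weights = _sample_points(geometry, frame_index,
                                  lo - grid_spec.voxel_size / 2,
                                  hi + grid_spec.voxel_size / 2, step,
                                  ray_subset)
    fidx = np.ascontiguousarray((pts - grid_spec.origin) / grid_spec.voxel_size)
    vol = volume_values if isinstance(volume_values, Tensor) \
        else Tensor(volume_values)
    shape = vol.data.shape
    out_data = _kernels.grid_project_fw(np.ascontiguousarray(vol.data),
                                        fidx, weights)

    def bw(g):
        gvol = _kernels.grid_project_bw(shape[0], shape[1], shape[2], fidx,
                                        weights, np.ascontiguousarray(g))
        vol._accum(gvol)

    if vol.requires_grad:
        return Tensor._node(out_data, (vol,), bw)
    return Tensor(out_data)


def simulate_projections(volume_at_frame: Callable[[int], VolumeGrid],
                         geometry: ScanGeometry, noise_sigma: float = 0.0,
                         rng: np.random.Generator | None = None) -> ProjectionSet:
    """Project a (possibly time-varying) volume at every frame of a scan."""
    frames = np.empty((geometry.n_frames, geometry.det_nu, geometry.det_nv))
    for k in range(geometry.n_frames):
        frames[k] = forward_project_grid(volume_at_frame(k), geometry, k)
    if noise_sigma > 0:
        if rng is None:
            rng = np.random.default_rng()
        frames = frames + rng.normal(0.0, noise_sigma, frames.shape)
    return ProjectionSet(frames, geometry)
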