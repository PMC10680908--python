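"""Training objectives: image fidelity, projection fidelity, total variation.

All losses are mean-normalized (per voxel or per pixel) and return autodiff
Tensors so they can be combined and differentiated.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, as_tensor
from .bspline import MotionBasisSet, compose_dvf, mbc_orthonormality_loss
from .fields import SpatialField, TemporalField
from .geometry import ProjectionSet, VolumeGrid
from .projector import forward_project_field, forward_project_voxels

__all__ = ["loss_image_fidelity", "loss_total_variation",
           "loss_projection_fidelity", "mbc_orthonormality_loss"]


def loss_image_fidelity(field: SpatialField, target: VolumeGrid,
                        points_mm: np.ndarray | None = None,
                        values: np.ndarray | None = None) -> Tensor:
    """Mean squared error between the field and a target volume.

    By default all voxel centers of ``target`` are used; a (points, values)
    subset can be supplied for mini-batched fitting.
    """
    if points_mm is None:
        points_mm = target.voxel_centers()
        values = target.values.ravel()
    if points_mm.shape[0] != values.shape[0]:
        raise ValueError("points/values size mismatch")
    pred = field(points_mm)
    return (pred - values).square().mean()


def _forward_diff(x: Tensor, axis: int) -> Tensor:
    """Forward finite difference along ``axis``; zero at the trailing face."""
    n = x.data.shape[axis]
    sl_hi = [slice(None)] * x.data.ndim
    sl_lo = [slice(None)] * x.data.ndim
    sl_hi[axis] = slice(1, n)
    sl_lo[axis] = slice(0, n - 1)
    sl_hi, sl_lo = tuple(sl_hi), tuple(sl_lo)
    d = np.zeros_like(x.data)
    d[sl_lo] = x.data[sl_hi] - x.data[sl_lo]

    def bw(g):
        gx = np.zeros_like(x.data)
        gx[sl_hi] += g[sl_lo]
        gx[sl_lo] -= g[sl_lo]
        x._accum(gx)

    if x.requires_grad:
        return Tensor._node(d, (x,), bw)
    return Tensor(d)


def loss_total_variation(field: SpatialField, eval_grid: VolumeGrid,
                         stride: int = 1) -> Tensor:
    """Isotropic total variation of the reference field on a sampled grid.

    Forward (undivided) finite differences, isotropic magnitude
    sqrt(gx^2 + gy^2 + gz^2), averaged over the grid.  ``stride`` subsamples
    the evaluation lattice for cheaper per-step regularization.
    """
    dims = tuple((d + stride - 1) // stride for d in eval_grid.dims)
    if min(dims) < 2:
        raise ValueError("TV evaluation grid needs at least 2 voxels per axis")
    sub = VolumeGrid.empty(dims, eval_grid.voxel_size * stride,
                           center=eval_grid.center())
    vals = field(sub.voxel_centers()).reshape(*dims)
    gx = _forward_diff(vals, 0)
    gy = _forward_diff(vals, 1)
    gz = _forward_diff(vals, 2)
    mag = (gx.square() + gy.square() + gz.square() + 1e-24).sqrt()
    return mag.mean()


def loss_projection_fidelity(spatial: SpatialField, projections: ProjectionSet,
                             frame_rays: list[tuple[int, np.ndarray]],
                             step: float,
                             temporal: TemporalField | None = None,
                             basis: MotionBasisSet | None = None,
                             grid: VolumeGrid | None = None) -> Tensor:
    """Projection-domain data fidelity on a mini-batch of rays.

    ``frame_rays`` lists (frame_index, flat pixel indices) pairs; the loss is
    the mean squared difference between rendered line integrals and the
    measured pixels over all requested rays.  When ``temporal`` and ``basis``
    are given the reference field is warped by the composed DVF of each
    frame before projection (the dynamic data term); otherwise the static
    reference is projected.

    When ``grid`` is given (the training path), the warped field is sampled
    at the grid's voxel centers and projected through the voxel-grid
    operator — the same operator that produces measured projections, so the
    rendered and measured radiographs share one discretization.  Without a
    grid, the continuous field projector is used directly.
    """
    if not frame_rays or any(len(r) == 0 for _, r in frame_rays):
        raise ValueError("empty ray batch")
    if (temporal is None) != (basis is None):
        raise ValueError("temporal field and motion basis must be given together")
    geom = projections.geometry
    box_lo, box_hi = spatial.box_lo, spatial.box_hi
    extent = box_hi - box_lo
    half = extent / 2.0  # basis fields are in box units; displacement in mm
    total = None
    n_rays = 0
    pts_grid = grid.voxel_centers() if grid is not None else None
    for frame, rays in frame_rays:
        coeffs = None
        if temporal is not None:
            coeffs = temporal(float(frame)).reshape(3, 3)
        if grid is not None:
            if coeffs is not None:
                q = np.clip((pts_grid - box_lo) / extent, 0.0, 1.0)
                disp = compose_dvf(coeffs, basis, q) * half
                vals = spatial(Tensor(pts_grid) + disp)
            else:
                vals = spatial(pts_grid)
            drr = forward_project_voxels(vals.reshape(*grid.dims), grid, geom,
                                         frame, step, ray_subset=rays)
        else:
            dvf = None
            if coeffs is not None:
                def dvf(pts, _c=coeffs):
                    q = np.clip((pts.data - box_lo) / extent, 0.0, 1.0)
                    return compose_dvf(_c, basis, q) * half

            drr = forward_project_field(spatial, geom, frame, box_lo, box_hi,
                                        step, dvf=dvf, ray_subset=rays)
        resid = drr - projections.frames[frame].ravel()[rays]
        sq = resid.square().sum()
        total = sq if total is None else total + sq
        n_rays += len(rays)
    return total * (1.0 / n_rays)
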