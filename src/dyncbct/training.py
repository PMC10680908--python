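"""Three-stage progressive optimization of the dynamic reconstruction model.

Stage I initializes the reference-volume field: first by fitting the
motion-averaged FDK volume in the image domain, then by projection-domain
refinement with total-variation regularization.  Stage II freezes the
reference field and initializes the temporal field and the B-spline motion
basis, unfreezing the basis resolutions coarse-to-fine.  Stage III unfreezes
everything for joint training.  All randomness (parameter init, ray
sampling, batch order) derives from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .autodiff import Adam, Tensor
from .bspline import MotionBasisSet, compose_dvf, mbc_orthonormality_loss
from .encoding import HashEncoderConfig
from .fdk import fdk_reconstruct
from .fields import SpatialField, TemporalField
from .geometry import ProjectionSet, VolumeGrid
from .losses import (loss_image_fidelity, loss_projection_fidelity,
                     loss_total_variation)

__all__ = ["LossWeights", "StageSchedule", "DynamicModel", "run_stage1",
           "run_stage2", "run_stage3", "reconstruct_dynamic", "warp_sample"]


@dataclass
class LossWeights:
    """Regularization weights (projection fidelity has implicit weight 1).

    ``lambda_temporal`` penalizes the mean squared frame-to-frame difference
    of the temporal coefficients.  At full frame counts the temporal hash
    grid averages several frames per cell and no explicit penalty is needed
    (default 0); reduced-frame desk-scale runs set it > 0 to stand in for
    that missing data density, otherwise the per-frame coefficients fit ray
    batches as temporally incoherent noise.
    """

    lambda_tv: float = 1e-3
    lambda_mbc: float = 1.0
    lambda_temporal: float = 0.0

    def __post_init__(self):
        if min(self.lambda_tv, self.lambda_mbc, self.lambda_temporal) < 0:
            raise ValueError("loss weights must be nonnegative")


@dataclass
class StageSchedule:
    """Epoch counts and learning rates of the three training stages.

    The defaults are the full-scale settings; ``epoch_scale`` shrinks every
    epoch count proportionally for small desk-scale runs.  An epoch of a
    projection-domain phase is one pass over all frames, each contributing a
    mini-batch of ``rays_per_frame`` randomly sampled detector pixels; an
    epoch of the image-domain phase is one pass over all voxels in random
    batches of ``voxel_batch``.
    """

    stage1_epochs: tuple[int, int] = (1000, 600)
    stage2_temporal_epochs: int = 100
    stage2_epochs_per_scale: int = 100
    stage2_finetune_epochs: int = 50
    stage3_epochs: int = 2000
    chunk_frames: int = 10
    basis_lr_boost: float = 10.0   # basis phases: gradient scales with |w|
    lr_spatial: tuple[float, float, float, float] = (4e-4, 1e-7, 1e-8, 5e-9)
    lr_temporal_and_mbc: tuple[float, float] = (2e-3, 2e-4)
    rays_per_frame: int = 2048
    voxel_batch: int = 8192
    ray_step_mm: float | None = None   # default: half the smallest voxel size
    tv_stride: int = 1
    motion_ray_fraction: float = 0.5   # rays drawn from the motion-active region
    epoch_scale: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if min(*self.stage1_epochs, self.stage2_epochs_per_scale,
               self.stage2_finetune_epochs, self.stage3_epochs) < 0:
            raise ValueError("epoch counts must be nonnegative")
        if min(*self.lr_spatial, *self.lr_temporal_and_mbc) <= 0:
            raise ValueError("learning rates must be positive")

    def scaled(self, n: int) -> int:
        return int(round(n * self.epoch_scale))


@dataclass
class DynamicModel:
    """The trained components plus the grid they were optimized on."""

    spatial: SpatialField
    temporal: TemporalField | None
    basis: MotionBasisSet | None
    grid: VolumeGrid
    loss_log: list[dict] = dc_field(default_factory=list)

    def dvf_fn(self, t: float):
        """Continuous DVF d(., t) as a callable on mm point Tensors."""
        if self.temporal is None or self.basis is None:
            raise ValueError("model has no motion components")
        coeffs = self.temporal(float(t)).reshape(3, 3)
        lo, hi = self.spatial.box_lo, self.spatial.box_hi
        half = (hi - lo) / 2.0  # basis fields are in box units

        def dvf(pts):
            data = pts.data if isinstance(pts, Tensor) else np.asarray(pts)
            q = np.clip((data - lo) / (hi - lo), 0.0, 1.0)
            return compose_dvf(coeffs, self.basis, q) * half

        return dvf


def warp_sample(reference_field: SpatialField, dvf, coords_mm) -> Tensor:
    """Attenuation of the warped reference: field(x + dvf(x)).

    Backward-warp convention; ``dvf`` maps point Tensors to mm displacement
    Tensors (or is None for the identity warp).
    """
    pts = coords_mm if isinstance(coords_mm, Tensor) else Tensor(np.atleast_2d(coords_mm))
    if dvf is not None:
        pts = pts + dvf(pts)
    return reference_field(pts)


def _log(model_log: list[dict], stage: str, epoch: int, lr: float,
         components: dict[str, float]) -> None:
    row = {"stage": stage, "epoch": epoch, "lr": lr}
    row.update(components)
    row["total"] = sum(components.values())
    model_log.append(row)


def _ray_step(schedule: StageSchedule, grid: VolumeGrid) -> float:
    return schedule.ray_step_mm or 0.5 * float(grid.voxel_size.min())


def _motion_pixel_weights(projections: ProjectionSet) -> np.ndarray:
    """Sampling distribution over detector pixels for the motion stages.

    Proportional to the temporal standard deviation of each pixel across the
    scan: in a rotating acquisition most of that variation is angular, but
    the ratio still concentrates probability on rows/regions swept by moving
    edges (diaphragm, tumor), where the per-frame motion residual lives.
    """
    std = projections.frames.std(axis=0).ravel()
    w = std + 1e-12
    return w / w.sum()


def _draw_rays(rng, n_pix: int, n_rays: int, frac_motion: float,
               motion_w: np.ndarray | None) -> np.ndarray:
    """Mixed uniform / motion-weighted ray batch (without replacement)."""
    if motion_w is None or frac_motion <= 0:
        return rng.choice(n_pix, size=n_rays, replace=False)
    n_m = min(int(round(n_rays * frac_motion)), n_rays)
    picked = rng.choice(n_pix, size=n_m, replace=False, p=motion_w)
    n_u = n_rays - n_m
    if n_u > 0:
        rest = rng.choice(n_pix, size=n_u, replace=False)
        picked = np.unique(np.concatenate([picked, rest]))
    return picked


def run_stage1(projections: ProjectionSet, grid: VolumeGrid,
               schedule: StageSchedule, weights: LossWeights,
               spatial_config: HashEncoderConfig | None = None,
               omega0: float = 30.0,
               fdk_volume: VolumeGrid | None = None
               ) -> tuple[SpatialField, list[dict]]:
    """Stage I: initialize the reference-volume field.

    Step 1 fits the field to the motion-averaged FDK reconstruction in the
    image domain; step 2 refines it against the measured projections with TV
    regularization.  Returns the field and the per-epoch loss log.
    """
    rng = np.random.default_rng(schedule.seed)
    spatial = SpatialField.for_volume(grid, encoder_config=spatial_config,
                                      omega0=omega0, rng=rng)
    log: list[dict] = []
    n1 = schedule.scaled(schedule.stage1_epochs[0])
    n2 = schedule.scaled(schedule.stage1_epochs[1])

    if n1 > 0:
        from scipy.ndimage import map_coordinates

        approx = fdk_volume if fdk_volume is not None else \
            fdk_reconstruct(projections, grid)
        pts = approx.voxel_centers()
        opt = Adam(spatial.parameters, lr=schedule.lr_spatial[0])
        n_vox = pts.shape[0]
        for epoch in range(n1):
            order = rng.permutation(n_vox)
            acc = 0.0
            for s in range(0, n_vox, schedule.voxel_batch):
                sel = order[s:s + schedule.voxel_batch]
                # jitter targets within voxels: the field must agree with the
                # (trilinear) target volume between voxel centers too, or the
                # inter-voxel freedom biases the rendered radiographs
                p = pts[sel] + rng.uniform(-0.5, 0.5, (len(sel), 3)) \
                    * approx.voxel_size
                idx = (p - approx.origin) / approx.voxel_size
                tgt = map_coordinates(approx.values, idx.T, order=1,
                                      mode="nearest")
                loss = loss_image_fidelity(spatial, approx, p, tgt)
                opt.zero_grad()
                loss.backward()
                opt.step()
                acc += loss.data * len(sel)
            if np.isnan(acc):
                raise FloatingPointError("stage I step 1 diverged (loss is NaN)")
            _log(log, "I.1", epoch, opt.lr, {"img": acc / n_vox})

    if n2 > 0:
        opt = Adam(spatial.parameters, lr=schedule.lr_spatial[1])
        step = _ray_step(schedule, grid)
        n_pix = projections.geometry.det_nu * projections.geometry.det_nv
        n_rays = min(schedule.rays_per_frame, n_pix)
        for epoch in range(n2):
            acc_p = acc_tv = 0.0
            frames = rng.permutation(projections.frame_count)
            for fr in frames:
                rays = rng.choice(n_pix, size=n_rays, replace=False)
                lp = loss_projection_fidelity(spatial, projections,
                                              [(int(fr), rays)], step,
                                              grid=grid)
                ltv = loss_total_variation(spatial, grid, schedule.tv_stride)
                loss = lp + weights.lambda_tv * ltv
                opt.zero_grad()
                loss.backward()
                opt.step()
                acc_p += lp.data
                acc_tv += weights.lambda_tv * ltv.data
            if np.isnan(acc_p):
                raise FloatingPointError("stage I step 2 diverged (loss is NaN)")
            nf = len(frames)
            _log(log, "I.2", epoch, opt.lr, {"prj": acc_p / nf, "tv": acc_tv / nf})
    return spatial, log


def _frame_ray_sets(projections, schedule, rng,
                    saliency: bool = False) -> list[np.ndarray]:
    """One fixed ray batch per frame.

    Drawing the batches once makes each frame's data term deterministic
    across epochs; re-drawing every epoch injects sampling noise larger than
    the per-frame motion signal at small batch sizes.

    ``saliency`` selects, per frame, the detector pixels that deviate most
    from the slow gantry-rotation trend of the pixel's time series (plus a
    uniform remainder).  Those pixels are where the frame's *motion*
    residual lives, so concentrating the data term on them counteracts the
    amplitude damping that static anatomy exerts on the early rigid-like
    registration.  With default settings it is also mixed with
    motion-weighted sampling for the non-saliency share.
    """
    from scipy.ndimage import gaussian_filter1d

    n_pix = projections.geometry.det_nu * projections.geometry.det_nv
    n_rays = min(schedule.rays_per_frame, n_pix)
    nf = projections.frame_count
    if saliency and n_rays < n_pix:
        trend = gaussian_filter1d(projections.frames,
                                  max(2.0, nf / 9.0), axis=0, mode="nearest")
        detr = np.abs(projections.frames - trend).reshape(nf, -1)
        n_sal = int(round(n_rays * 0.75))
        sets = []
        for k in range(nf):
            top = np.argsort(detr[k])[-n_sal:]
            uni = rng.choice(n_pix, n_rays - n_sal, replace=False)
            sets.append(np.unique(np.concatenate([top, uni])))
        return sets
    motion_w = _motion_pixel_weights(projections) if n_rays < n_pix else None
    return [_draw_rays(rng, n_pix, n_rays, schedule.motion_ray_fraction,
                       motion_w) for _ in range(nf)]


def _stage_epoch(spatial, temporal, basis, projections, schedule, weights,
                 grid, opts, rng, step, frame_rays):
    """One projection-domain epoch of Stage II/III; returns loss components.

    Frames are visited in random order in chunks of ``chunk_frames``; each
    optimizer step accumulates the data term over one chunk (plus the
    regularizers), which averages out the conflicting per-frame updates to
    the shared temporal network.
    """
    acc = {"prj": 0.0, "tv": 0.0, "mbc": 0.0, "tem": 0.0}
    nf = projections.frame_count
    order = rng.permutation(nf)
    all_t = np.arange(nf, dtype=float)
    K = max(1, schedule.chunk_frames)
    for s in range(0, nf, K):
        chunk = order[s:s + K]
        batch = [(int(fr), frame_rays[fr]) for fr in chunk]
        lp = loss_projection_fidelity(spatial, projections, batch, step,
                                      temporal=temporal, basis=basis,
                                      grid=grid)
        ltv = loss_total_variation(spatial, grid, schedule.tv_stride)
        lmbc = mbc_orthonormality_loss(basis)
        loss = lp + weights.lambda_tv * ltv + weights.lambda_mbc * lmbc
        ltem = None
        if weights.lambda_temporal > 0:
            w_all = temporal(all_t).reshape(nf, 9)
            ltem = (w_all[1:, :] - w_all[:-1, :]).square().mean()
            loss = loss + weights.lambda_temporal * ltem
        for opt in opts:
            opt.zero_grad()
        loss.backward()
        for opt in opts:
            opt.step()
        acc["prj"] += lp.data * len(chunk)
        acc["tv"] += weights.lambda_tv * ltv.data * len(chunk)
        acc["mbc"] += weights.lambda_mbc * lmbc.data * len(chunk)
        if ltem is not None:
            acc["tem"] += weights.lambda_temporal * ltem.data * len(chunk)
    if np.isnan(acc["prj"]):
        raise FloatingPointError("projection-domain training diverged (loss is NaN)")
    return {k: v / nf for k, v in acc.items()}


def run_stage2(spatial: SpatialField, projections: ProjectionSet,
               grid: VolumeGrid, schedule: StageSchedule, weights: LossWeights,
               temporal_config: HashEncoderConfig | None = None,
               mbc_counts: tuple[int, int, int] = (6, 10, 17),
               mbc_init_std: float = 0.05,
               ) -> tuple[TemporalField, MotionBasisSet, list[dict]]:
    """Stage II: motion initialization with the reference field frozen.

    Progressive, block-coordinate schedule: (0) a temporal-only phase on
    motion-salient rays with the basis frozen at its axis-aligned
    orthonormal initialization and only the SI (dominant respiratory)
    coefficient heads free — a per-frame rigid registration that anchors
    the breathing trace; (1-3) the basis resolutions unfreeze coarse to
    fine, each basis phase followed by a short temporal refresh; (4) a
    joint finetune of all motion parameters.  Alternating the two factor
    blocks of the bilinear coefficient-times-basis product is markedly more
    stable than joint updates at small step counts.  The reference-field
    parameters are excluded from optimization throughout.
    """
    rng = np.random.default_rng(schedule.seed + 1)
    temporal = TemporalField(projections.frame_count,
                             encoder_config=temporal_config, rng=rng)
    basis = MotionBasisSet.create(mbc_counts, init_std=mbc_init_std, rng=rng)
    log: list[dict] = []
    # freeze the spatial field: gradients still flow *through* it to the
    # motion parameters, but its own parameters receive no updates
    for p in spatial.parameters:
        p.requires_grad = False
    step = _ray_step(schedule, grid)
    sal_rays = _frame_ray_sets(projections, schedule, rng, saliency=True)
    full_rays = _frame_ray_sets(projections, schedule, rng, saliency=False)
    lr = schedule.lr_temporal_and_mbc[0]
    n_tem = schedule.scaled(schedule.stage2_temporal_epochs)
    n_scale = schedule.scaled(schedule.stage2_epochs_per_scale)
    n_ft = schedule.scaled(schedule.stage2_finetune_epochs)
    n_refresh = max(1, n_scale // 2)
    si_axis = 2  # z is superior-inferior in the world convention
    si_heads = [p for i in range(3)
                for p in temporal.heads[i * 3 + si_axis].parameters]
    si_heads += temporal.encoder.parameters
    all_params = temporal.parameters + basis.parameters

    def set_trainable(params):
        for p in all_params:
            p.requires_grad = False
        for p in params:
            p.requires_grad = True

    def run_phase(n, params, phase_lr, rays, tag, epoch):
        set_trainable(params)
        opt = Adam(params, lr=phase_lr)
        for _ in range(n):
            comps = _stage_epoch(spatial, temporal, basis, projections,
                                 schedule, weights, grid, [opt], rng, step,
                                 rays)
            _log(log, tag, epoch, phase_lr, comps)
            epoch += 1
        return epoch

    epoch = 0
    epoch = run_phase(n_tem, si_heads, lr, sal_rays, "II.temporal", epoch)
    basis_lr = lr * schedule.basis_lr_boost
    for active in range(3):  # unfreeze basis resolutions coarse -> fine
        epoch = run_phase(n_scale, [basis.grids[active].control_values],
                          basis_lr, full_rays, f"II.scale{active + 1}", epoch)
        epoch = run_phase(n_refresh, si_heads, lr, sal_rays,
                          f"II.refresh{active + 1}", epoch)
    epoch = run_phase(n_ft, all_params, lr * 0.5, full_rays, "II.finetune",
                      epoch)
    for p in all_params:
        p.requires_grad = True
    for p in spatial.parameters:
        p.requires_grad = True
    return temporal, basis, log


def run_stage3(spatial: SpatialField, temporal: TemporalField,
               basis: MotionBasisSet, projections: ProjectionSet,
               grid: VolumeGrid, schedule: StageSchedule,
               weights: LossWeights) -> list[dict]:
    """Stage III: joint training of all components (in place)."""
    rng = np.random.default_rng(schedule.seed + 2)
    step = _ray_step(schedule, grid)
    n3 = schedule.scaled(schedule.stage3_epochs)
    if n3 == 0:
        return []
    opt_spa = Adam(spatial.parameters, lr=schedule.lr_spatial[3])
    opt_mot = Adam(temporal.parameters + basis.parameters,
                   lr=schedule.lr_temporal_and_mbc[1])
    frame_rays = _frame_ray_sets(projections, schedule, rng)
    log: list[dict] = []
    for epoch in range(n3):
        comps = _stage_epoch(spatial, temporal, basis, projections, schedule,
                             weights, grid, [opt_spa, opt_mot], rng, step,
                             frame_rays)
        _log(log, "III", epoch, opt_mot.lr, comps)
    return log


def reconstruct_dynamic(model: DynamicModel, times, grid: VolumeGrid,
                        clamp_negative: bool = True
                        ) -> tuple[list[VolumeGrid], list[np.ndarray]]:
    """Sample dynamic volumes I(x, t) and DVFs d(x, t) on a grid.

    ``times`` may be any real frame indices within [0, n_frames - 1]; the
    representation is continuous in both space and time, so any grid
    resolution and time sampling is permitted.
    """
    n_frames = model.temporal.n_frames if model.temporal is not None else 1
    times = np.atleast_1d(np.asarray(times, dtype=float))
    if np.any((times < 0) | (times > n_frames - 1)):
        raise ValueError(f"times must lie within [0, {n_frames - 1}]")
    pts = grid.voxel_centers()
    volumes, dvfs = [], []
    for t in times:
        dvf = model.dvf_fn(t) if model.temporal is not None else None
        disp = dvf(Tensor(pts)).data if dvf is not None else np.zeros_like(pts)
        vals = model.spatial(pts + disp).data
        if clamp_negative:
            vals = np.maximum(vals, 0.0)
        volumes.append(grid.like(vals.reshape(grid.dims)))
        dvfs.append(disp.reshape(*grid.dims, 3))
    return volumes, dvfs
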