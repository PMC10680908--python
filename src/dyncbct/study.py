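"""Self-contained phantom studies: simulate, reconstruct, evaluate.

These functions bundle the package's end-to-end workflows at a fixed
desk-scale problem size (32 x 32 x 16 voxels at 12 mm, 64 x 32 detector at
9 mm, 110 frames over a 60 s / 360 degree scan, reduced epoch schedule) so
that a full dynamic-reconstruction study runs in minutes on one CPU.  The
motion scenarios themselves keep their clinical-scale parameters (13 mm
quasi-periodic breathing and its variants).
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor
from .geometry import ScanGeometry, VolumeGrid, build_trajectory
from .metrics import (TrackedTrace, com_error, compare_traces, dice,
                      propagate_mask, relative_error, segment_blob_near,
                      ssim_volume)
from .phantom import (MotionScenario, render_phantom_volume, simulate_scan,
                      thorax_phantom)
from .training import (DynamicModel, LossWeights, StageSchedule,
                       reconstruct_dynamic, run_stage1, run_stage2, run_stage3)

__all__ = ["desk_schedule", "desk_setup", "static_study", "dynamic_study"]


DESK_MBC_COUNTS = (5, 8, 12)  # finest control spacing ~ tumor diameter


def desk_schedule(seed: int, **overrides) -> StageSchedule:
    """The reduced desk-scale training schedule (see docs/methods.md)."""
    kw = dict(
        stage1_epochs=(40, 4),
        stage2_temporal_epochs=45,
        stage2_epochs_per_scale=2,
        stage2_finetune_epochs=2,
        stage3_epochs=4,
        lr_spatial=(4e-4, 1e-7, 1e-8, 5e-9),
        lr_temporal_and_mbc=(2e-3, 2e-4),
        rays_per_frame=512,
        tv_stride=2,
        chunk_frames=10,
        seed=seed,
    )
    kw.update(overrides)
    return StageSchedule(**kw)


def desk_setup(scenario_mode: str, seed: int, n_frames: int = 110):
    """Simulate a desk-scale scan of the thorax phantom."""
    grid = VolumeGrid.empty((32, 32, 16), 12.0, center=(0.0, 0.0, 0.0))
    spec = thorax_phantom()
    scenario = MotionScenario.preset(scenario_mode, seed=seed)
    angles, ts = build_trajectory(60.0, 360.0, n_frames / 60.0)
    geom = ScanGeometry(1000.0, 1500.0, 64, 32, 9.0, 9.0, angles, ts)
    projections, truth = simulate_scan(spec, scenario, geom, grid, seed=seed)
    return spec, grid, geom, projections, truth


def static_study(seed: int) -> dict:
    """Stage I alone on a static phantom: reference recovery quality.

    Returns the relative error of the reconstructed reference volume against
    the rendered static phantom.
    """
    spec, grid, geom, projections, truth = desk_setup("static", seed)
    # static scans carry no motion that projection-domain refinement could
    # absorb, so step 2 runs at a desk-scale learning rate and acts as plain
    # iterative reconstruction on top of FDK
    schedule = desk_schedule(seed, stage1_epochs=(40, 10),
                             lr_spatial=(4e-4, 1e-4, 1e-8, 5e-9))
    weights = LossWeights()
    spatial, log = run_stage1(projections, grid, schedule, weights)
    recon = spatial.sample_volume(grid)
    gt = truth.volume_at(0)
    return {
        "re": relative_error([recon], [gt]),
        "ssim": ssim_volume(recon, gt),
        "n_frames": projections.frame_count,
        "grid_dims": grid.dims,
        "loss_log": log,
    }


def dynamic_study(scenario_mode: str, seed: int,
                  eval_voxel_mm: float = 6.0,
                  image_metric_stride: int = 10) -> dict:
    """Full three-stage reconstruction of a breathing scan, with evaluation.

    The solved tumor motion is evaluated by contouring the tumor in the
    reference volume (seeded at the known resting tumor position, standing
    in for the clinical contour), propagating the contour to every frame by
    the solved deformation fields, and comparing center-of-mass trajectories
    and mask overlap against the simulation ground truth.  Masks are
    evaluated on a finer grid than the reconstruction grid — the continuous
    representation can be sampled at any resolution.
    """
    spec, grid, geom, projections, truth = desk_setup(scenario_mode, seed)
    schedule = desk_schedule(seed)
    weights = LossWeights(lambda_temporal=10.0)
    spatial, log1 = run_stage1(projections, grid, schedule, weights)
    temporal, basis, log2 = run_stage2(spatial, projections, grid, schedule,
                                       weights, mbc_counts=DESK_MBC_COUNTS)
    log3 = run_stage3(spatial, temporal, basis, projections, grid, schedule,
                      weights)
    model = DynamicModel(spatial, temporal, basis, grid, log1 + log2 + log3)

    nf = projections.frame_count
    fine_dims = tuple(int(round(d * grid.voxel_size[k] / eval_voxel_mm))
                      for k, d in enumerate(grid.dims))
    fine = VolumeGrid.empty(fine_dims, eval_voxel_mm, center=grid.center())
    ref_fine = spatial.sample_volume(fine)
    mask0 = segment_blob_near(ref_fine, spec.tumor().center)

    coms, comes, come_axes, dscs, valid = [], [], [], [], []
    for k in range(nf):
        pm = propagate_mask(mask0, model, k)
        ok = pm.values.sum() > 0 and truth.tumor_visible(k)
        valid.append(ok)
        if not ok:
            coms.append([np.nan] * 3)
            continue
        com = fine.origin + np.argwhere(pm.values > 0.5).mean(axis=0) \
            * fine.voxel_size
        coms.append(com)
        _, gt_mask, _ = render_phantom_volume(spec, truth.displacements[k],
                                              fine)
        gtm = fine.like(gt_mask.astype(float))
        d, mag = com_error(pm, gtm)
        comes.append(mag)
        come_axes.append(d)
        dscs.append(dice(pm, gtm))
    coms = np.asarray(coms)
    valid = np.asarray(valid)
    solved = TrackedTrace(coms[:, 2], valid=valid)
    reference = TrackedTrace(truth.com_trajectory[:, 2], valid=valid)
    pearson, mae = compare_traces(reference, solved)

    frames = list(range(0, nf, image_metric_stride))
    vols, _ = reconstruct_dynamic(model, frames, grid)
    gts = [truth.volume_at(k) for k in frames]
    come_axes = np.abs(np.asarray(come_axes))
    return {
        "pearson_si": pearson,
        "trace_mae_mm": mae,
        "come_mm": float(np.mean(comes)),
        "come_lr_mm": float(come_axes[:, 0].mean()),
        "come_ap_mm": float(come_axes[:, 1].mean()),
        "come_si_mm": float(come_axes[:, 2].mean()),
        "dsc": float(np.mean(dscs)),
        "re": relative_error(vols, gts),
        "ssim": float(np.mean([ssim_volume(v, g) for v, g in zip(vols, gts)])),
        "n_frames": nf,
        "grid_dims": grid.dims,
        "voxel_mm": float(grid.voxel_size[0]),
        "model": model,
        "truth": truth,
        "projections": projections,
    }
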