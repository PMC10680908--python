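"""Quantitative evaluation: image, motion and projection-domain metrics.

Image metrics: relative error (per-frame L2 residual over the truth norm,
averaged over frames) and 3D SSIM.  Motion metrics: tumor center-of-mass
error (COME), Dice similarity of propagated masks, and Pearson correlation
of motion traces.  Projection-domain tracking: the Amsterdam Shroud
respiratory trace and normalized-cross-correlation template tracking of
feature points, with the localization error statistic between matched
traces.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.ndimage import map_coordinates
from skimage.feature import match_template
from skimage.metrics import structural_similarity

from .autodiff import Tensor
from .geometry import ProjectionSet, VolumeGrid

__all__ = ["TrackedTrace", "relative_error", "ssim_volume", "com_error",
           "dice", "propagate_mask", "amsterdam_shroud_trace",
           "feature_point_le", "compare_traces", "track_template",
           "segment_blob_near"]


@dataclass
class TrackedTrace:
    """Per-frame tracked positions with a validity mask.

    ``positions`` has shape (n_frames,) or (n_frames, n_points); ``valid``
    marks frames where the tracked structure was in the field of view.
    """

    positions: np.ndarray
    valid: np.ndarray | None = None

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        if self.valid is None:
            self.valid = np.ones(self.positions.shape[0], dtype=bool)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.valid.shape[0] != self.positions.shape[0]:
            raise ValueError("validity mask length must equal frame count")
        if not np.all(np.isfinite(self.positions[self.valid])):
            raise ValueError("positions must be finite on valid frames")


def relative_error(estimate, truth) -> float:
    """Mean over frames of ||est - truth||_2 / ||truth||_2.

    Accepts sequences of VolumeGrid (or arrays); single volumes are treated
    as one-frame sequences.
    """
    def stack(x):
        if isinstance(x, VolumeGrid):
            return [x.values]
        return [v.values if isinstance(v, VolumeGrid) else np.asarray(v) for v in x]

    est, tru = stack(estimate), stack(truth)
    if len(est) != len(tru):
        raise ValueError("frame counts differ")
    res = []
    for e, g in zip(est, tru):
        if e.shape != g.shape:
            raise ValueError("volume dims differ")
        norm = np.sqrt((g**2).sum())
        if norm == 0:
            raise ZeroDivisionError("all-zero truth frame in relative error")
        res.append(np.sqrt(((e - g) ** 2).sum()) / norm)
    return float(np.mean(res))


def ssim_volume(estimate: VolumeGrid, truth: VolumeGrid) -> float:
    """3D SSIM with a Gaussian window; data range from the truth volume."""
    e, g = np.asarray(estimate.values), np.asarray(truth.values)
    if e.shape != g.shape:
        raise ValueError("volume dims differ")
    rng = float(g.max() - g.min())
    if rng == 0:
        rng = 1.0
    win = min(11, min(g.shape))
    if win % 2 == 0:
        win -= 1
    return float(structural_similarity(g, e, data_range=rng,
                                       gaussian_weights=True, sigma=1.5,
                                       use_sample_covariance=False,
                                       win_size=win))


def _centroid_mm(mask: VolumeGrid) -> np.ndarray:
    m = mask.values > 0.5
    if not m.any():
        raise ValueError("empty mask")
    idx = np.argwhere(m)
    return mask.origin + idx.mean(axis=0) * mask.voxel_size


def com_error(mask_a: VolumeGrid, mask_b: VolumeGrid
              ) -> tuple[np.ndarray, float]:
    """Centroid difference (LR, AP, SI) in mm and its magnitude."""
    d = _centroid_mm(mask_a) - _centroid_mm(mask_b)
    return d, float(np.linalg.norm(d))


def dice(mask_a, mask_b) -> float:
    """Dice similarity 2|A n B| / (|A| + |B|) of binary masks."""
    a = (mask_a.values if isinstance(mask_a, VolumeGrid) else np.asarray(mask_a)) > 0.5
    b = (mask_b.values if isinstance(mask_b, VolumeGrid) else np.asarray(mask_b)) > 0.5
    na, nb = a.sum(), b.sum()
    if na + nb == 0:
        raise ValueError("both masks are empty")
    return float(2.0 * (a & b).sum() / (na + nb))


def propagate_mask(reference_mask: VolumeGrid, model, t: float) -> VolumeGrid:
    """Warp a reference-frame mask to time t by the model's DVF.

    Backward warp: M(x, t) = M_ref(x + d(x, t)) interpolated as a continuous
    indicator and thresholded at 0.5.
    """
    pts = reference_mask.voxel_centers()
    disp = model.dvf_fn(t)(Tensor(pts)).data
    idx = reference_mask.world_to_index(pts + disp)
    vals = map_coordinates(reference_mask.values.astype(float), idx.T, order=1,
                           mode="constant", cval=0.0)
    return reference_mask.like((vals >= 0.5).astype(float).reshape(
        reference_mask.dims))


def segment_blob_near(volume: VolumeGrid, seed_mm, radius_mm: float = 30.0,
                      smooth_mm: float = 6.0) -> VolumeGrid:
    """Contour a bright blob around a seed point (half-maximum region).

    The reference-frame tumor is delineated the way a contour is drawn in
    practice: around a known approximate location.  Within ``radius_mm`` of
    the seed, the local background is estimated from the surrounding shell,
    and the mask is the connected region above the half-way level between
    background and local peak that contains the peak.  Works on
    motion-blurred references where the blob is a soft bump rather than a
    hard-edged sphere.
    """
    from scipy import ndimage

    seed_mm = np.asarray(seed_mm, dtype=float)
    sm = ndimage.gaussian_filter(volume.values,
                                 smooth_mm / volume.voxel_size)
    pts = volume.voxel_centers().reshape(*volume.dims, 3)
    d = np.linalg.norm(pts - seed_mm, axis=-1)
    core = d <= radius_mm
    if not core.any():
        raise ValueError("seed lies outside the volume")
    shell = (d > radius_mm) & (d <= 2.0 * radius_mm)
    bg = np.percentile(sm[shell], 25) if shell.any() else 0.0
    peak_idx = np.unravel_index(np.argmax(np.where(core, sm, -np.inf)),
                                volume.dims)
    peak = sm[peak_idx]
    if peak <= bg:
        raise ValueError("no blob above background near the seed")
    level = bg + 0.5 * (peak - bg)
    region = (sm >= level) & (d <= 2.0 * radius_mm)
    lab, _ = ndimage.label(region)
    mask = lab == lab[peak_idx]
    return volume.like(mask.astype(float))


def _parabolic_refine(y: np.ndarray, i: int) -> float:
    if 0 < i < len(y) - 1:
        denom = y[i - 1] - 2 * y[i] + y[i + 1]
        if abs(denom) > 1e-12:
            return i + 0.5 * (y[i - 1] - y[i + 1]) / denom
    return float(i)


def amsterdam_shroud_trace(projections: ProjectionSet,
                           band: tuple[int, int] | None = None,
                           sign: int = 1) -> TrackedTrace:
    """Respiratory SI trace from the Amsterdam Shroud image.

    Each projection is differentiated along the SI detector axis and summed
    over the lateral axis, giving one column of the shroud image; columns
    are z-score normalized, and the (sub-pixel refined) extremum inside the
    SI band gives the per-frame trace in detector mm.  ``band`` is a (lo,
    hi) SI pixel index range; by default the band around the row of maximal
    temporal variance is used.  ``sign`` selects a maximum (+1) or minimum
    (-1) of the normalized derivative.
    """
    if projections.frame_count < 2:
        raise ValueError("need at least 2 frames")
    g = projections.geometry
    # derivative along SI (v, axis 1), consolidated over lateral u (axis 0)
    shroud = np.diff(projections.frames, axis=2).sum(axis=1)  # (n, nv - 1)
    std = shroud.std(axis=1, keepdims=True)
    shroud = (shroud - shroud.mean(axis=1, keepdims=True)) / np.maximum(std, 1e-12)
    if band is None:
        var = (sign * shroud).var(axis=0)
        # pick a window around the most dynamic row
        half = max(4, shroud.shape[1] // 8)
        row = int(np.argmax(var))
        band = (max(0, row - half), min(shroud.shape[1], row + half))
    lo, hi = band
    if not (0 <= lo < hi <= shroud.shape[1]):
        raise ValueError(f"band {band} outside detector rows [0, {shroud.shape[1]}]")
    pos = np.empty(projections.frame_count)
    for k in range(projections.frame_count):
        col = sign * shroud[k, lo:hi]
        i = int(np.argmax(col))
        pos[k] = lo + _parabolic_refine(col, i) + 0.5  # diff sits between rows
    _, v = g.pixel_coordinates()
    mm = v[0] + pos * g.det_pitch_v
    return TrackedTrace(mm)


def track_template(frames: np.ndarray, frame0_center: tuple[int, int],
                   half_size: int = 8, search: int = 12,
                   pitch_v: float = 1.0) -> TrackedTrace:
    """Track a template patch through a projection sequence by NCC.

    The patch around ``frame0_center`` (u, v pixels) in frame 0 is matched
    in a local search window of every frame; the SI (v) position in detector
    mm is returned with parabolic sub-pixel refinement.  The same tracker
    configuration is used on measured projections and on re-projected DRRs.
    """
    cu, cv = frame0_center
    h = half_size
    tmpl = frames[0, cu - h:cu + h + 1, cv - h:cv + h + 1]
    n = frames.shape[0]
    pos = np.empty(n)
    valid = np.ones(n, dtype=bool)
    for k in range(n):
        lo_u, hi_u = cu - h - search, cu + h + search + 1
        lo_v, hi_v = cv - h - search, cv + h + search + 1
        lo_u, lo_v = max(lo_u, 0), max(lo_v, 0)
        win = frames[k, lo_u:hi_u, lo_v:hi_v]
        if win.shape[0] < tmpl.shape[0] or win.shape[1] < tmpl.shape[1]:
            valid[k] = False
            pos[k] = np.nan
            continue
        cc = match_template(win, tmpl)
        iu, iv = np.unravel_index(np.argmax(cc), cc.shape)
        iv_ref = _parabolic_refine(cc[iu, :], int(iv))
        pos[k] = (lo_v + iv_ref + h) * pitch_v
    return TrackedTrace(pos, valid)


def feature_point_le(reference_traces: list[TrackedTrace],
                     test_traces: list[TrackedTrace]) -> float:
    """Localization error between matched point traces (SI components, mm).

    Per frame, the mean over points of the absolute SI difference between
    the reference (projection-domain) and test (DRR-domain) locations;
    averaged over frames where all points are valid.
    """
    if len(reference_traces) != len(test_traces) or not reference_traces:
        raise ValueError("trace sets must be nonempty and matched")
    n = reference_traces[0].positions.shape[0]
    per_frame = []
    for k in range(n):
        diffs = []
        for r, t in zip(reference_traces, test_traces):
            if r.valid[k] and t.valid[k]:
                diffs.append(abs(r.positions[k] - t.positions[k]))
        if diffs:
            per_frame.append(np.mean(diffs))
    if not per_frame:
        raise ValueError("no frames with valid tracked points")
    return float(np.mean(per_frame))


def compare_traces(a: TrackedTrace, b: TrackedTrace
                   ) -> tuple[float, float]:
    """Pearson r and mean absolute error over common valid frames."""
    common = a.valid & b.valid
    if common.sum() < 3:
        raise ValueError("need at least 3 common valid frames")
    x, y = a.positions[common], b.positions[common]
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero-variance trace: correlation undefined")
    r = float(stats.pearsonr(x, y).statistic)
    return r, float(np.abs(x - y).mean())
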