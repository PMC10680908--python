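"""Feldkamp-Davis-Kress filtered backprojection for circular cone-beam scans.

Standard flat-panel FDK: cosine (cone/fan) pre-weighting, ramp filtering of
detector rows, and distance-weighted backprojection.  Short scans
(180 deg + fan <= arc < 360 deg) use Parker redundancy weights; offset-detector
(half-fan) scans use a smooth lateral feathering of the doubly-measured
central band.  Used here to build the motion-averaged volume that initializes
the reference-image representation.
"""

from __future__ import annotations

import numpy as np
from scipy.fft import irfft, rfft
from scipy.ndimage import map_coordinates

from .geometry import ProjectionSet, VolumeGrid

__all__ = ["fdk_reconstruct", "ramp_kernel"]


def ramp_kernel(n: int, spacing: float, apodization: str = "none") -> np.ndarray:
    """Frequency response of the discrete ramp filter (Ram-Lak) of length n.

    Built from the exact space-domain kernel so the DC term is handled
    correctly; optional Hann apodization tapers high frequencies.
    """
    k = np.arange(-(n // 2), n - n // 2)
    h = np.zeros(n)
    h[k == 0] = 1.0 / (4.0 * spacing**2)
    odd = k % 2 == 1
    h[odd] = -1.0 / (np.pi * k[odd] * spacing) ** 2
    H = np.real(rfft(np.fft.ifftshift(h), n=n))
    if apodization == "hann":
        f = np.linspace(0.0, 1.0, H.size)
        H = H * (0.5 + 0.5 * np.cos(np.pi * f))
    elif apodization != "none":
        raise ValueError(f"unknown apodization {apodization!r}")
    return H


def _parker_weights(beta: np.ndarray, gamma: np.ndarray, arc_rad: float) -> np.ndarray:
    """Parker short-scan redundancy weights, generalized to arcs > pi + fan."""
    gm = (arc_rad - np.pi) / 2.0  # effective half fan angle incl. over-scan
    b = beta[:, None]
    g = gamma[None, :]
    w = np.ones((beta.size, gamma.size))
    ramp_in = b < 2.0 * (gm - g)
    with np.errstate(divide="ignore", invalid="ignore"):
        w_in = np.sin(np.pi / 4.0 * b / np.maximum(gm - g, 1e-12)) ** 2
        w_out = np.sin(np.pi / 4.0 * (np.pi + 2 * gm - b) / np.maximum(gm + g, 1e-12)) ** 2
    ramp_out = b > np.pi - 2.0 * g
    w = np.where(ramp_in, w_in, w)
    w = np.where(ramp_out, w_out, w)
    return np.clip(w, 0.0, 1.0)


def _offset_weights(u_iso: np.ndarray, sad: float) -> np.ndarray:
    """Lateral feathering for an offset (half-fan) detector.

    The band measured on both sides of the central ray over a full rotation is
    down-weighted so conjugate rays sum to one; full-scan normalization then
    uses weight 1 (not 1/2) per frame.
    """
    overlap = min(abs(u_iso[0]), abs(u_iso[-1]))
    if overlap <= 0:
        return np.ones_like(u_iso)
    gamma = np.arctan2(u_iso, sad)
    gov = np.arctan2(overlap, sad)
    ramp = 0.5 * (np.sin(np.pi / 2.0 * np.clip(gamma / gov, -1.0, 1.0)) + 1.0)
    if abs(u_iso[0]) > abs(u_iso[-1]):  # detector shifted to -u: mirror ramp
        ramp = 1.0 - ramp
    return ramp


def fdk_reconstruct(projections: ProjectionSet, target: VolumeGrid,
                    apodization: str = "none", dvf_at_frame=None) -> VolumeGrid:
    """FDK reconstruction of a projection set onto the ``target`` grid spec.

    ``target`` supplies dims / voxel size / origin; its values are ignored.
    Raises ``ValueError`` when the arc is below the short-scan minimum
    (180 deg + fan angle).

    ``dvf_at_frame``, if given, maps a frame index to a displacement array
    (nx, ny, nz, 3) in mm at the voxel centers; each frame is then
    backprojected at the warped voxel positions (motion-compensated FDK),
    which de-blurs moving structures given an estimate of the intra-scan
    motion.
    """
    geom = projections.geometry
    if projections.frame_count < 2:
        raise ValueError("FDK needs at least 2 frames")
    angles = geom.angles
    arc_deg = abs(angles[-1] - angles[0]) * geom.n_frames / max(geom.n_frames - 1, 1)
    arc_rad = np.deg2rad(arc_deg)
    full_scan = arc_deg >= 360.0 - 1e-6
    if not full_scan and arc_deg < 180.0 + geom.fan_angle_deg - 1e-9:
        raise ValueError(
            f"arc {arc_deg:.1f} deg below short-scan minimum "
            f"{180.0 + geom.fan_angle_deg:.1f} deg")

    mag = geom.sad / geom.sdd  # rescale detector to the isocenter plane
    u_det, v_det = geom.pixel_coordinates()
    u, v = u_det * mag, v_det * mag
    du = geom.det_pitch_u * mag

    cosw = geom.sad / np.sqrt(geom.sad**2 + u[:, None] ** 2 + v[None, :] ** 2)
    nfft = int(2 ** np.ceil(np.log2(2 * geom.det_nu)))
    H = ramp_kernel(nfft, du, apodization)

    if full_scan:
        frame_w = np.full(geom.n_frames, 0.5)
        parker = None
    else:
        beta = np.deg2rad(np.abs(angles - angles[0]))
        sign = 1.0 if angles[-1] >= angles[0] else -1.0
        gamma = sign * np.arctan2(u, geom.sad)
        parker = _parker_weights(beta, gamma, arc_rad)
        frame_w = np.ones(geom.n_frames)
    if geom.fan_mode == "half" or abs(geom.det_offset_u) > 1e-9:
        offset_w = _offset_weights(u, geom.sad)
        frame_w = frame_w * 2.0 if full_scan else frame_w
    else:
        offset_w = None

    out = VolumeGrid.empty(target.dims, target.voxel_size,
                           center=target.center())
    xc, yc, zc = out.axis_coords()
    X, Y = np.meshgrid(xc, yc, indexing="ij")
    Z = zc
    vox = out.voxel_centers() if dvf_at_frame is not None else None
    vol = np.zeros(out.dims)
    dbeta = arc_rad / geom.n_frames

    iu_scale = 1.0 / du
    iv_scale = 1.0 / (geom.det_pitch_v * mag)
    u0, v0 = u[0], v[0]

    for kf in range(geom.n_frames):
        p = projections.frames[kf] * cosw
        if offset_w is not None:
            p = p * offset_w[:, None]
        if parker is not None:
            p = p * parker[kf][:, None]
        Q = irfft(rfft(p, n=nfft, axis=0) * H[:, None], n=nfft, axis=0)[:geom.det_nu]
        Q *= du

        th = np.deg2rad(geom.angles[kf])
        c, s = np.cos(th), np.sin(th)
        if dvf_at_frame is not None:
            W = vox + dvf_at_frame(kf).reshape(-1, 3)
            xr = c * W[:, 0] + s * W[:, 1]
            yr = -s * W[:, 0] + c * W[:, 1]
            U = geom.sad - yr
            iu = (geom.sad * xr / U - u0) * iu_scale
            iv = (geom.sad * W[:, 2] / U - v0) * iv_scale
            w2 = (geom.sad**2 / U**2).reshape(out.dims)
            vals = map_coordinates(Q, [iu, iv], order=1, mode="constant",
                                   cval=0.0).reshape(out.dims)
            vol += frame_w[kf] * dbeta * w2 * vals
            continue
        xr = c * X + s * Y
        yr = -s * X + c * Y
        U = geom.sad - yr
        au = geom.sad * xr / U           # (nx, ny)
        w2 = geom.sad**2 / U**2
        iu = (au - u0) * iu_scale
        for kz, z in enumerate(Z):
            bv = geom.sad * z / U
            iv = (bv - v0) * iv_scale
            vals = map_coordinates(Q, [iu.ravel(), iv.ravel()], order=1,
                                   mode="constant", cval=0.0).reshape(iu.shape)
            vol[:, :, kz] += frame_w[kf] * dbeta * w2 * vals
    out.values[:] = vol
    return out
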