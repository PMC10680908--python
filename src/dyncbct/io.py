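"""File formats: projection stacks + geometry sidecars, volumes, checkpoints.

Projections travel as multi-frame TIFF or raw float32 stacks next to a
YAML geometry sidecar; volumes as NIfTI or MetaImage (via SimpleITK) with
voxel size and origin preserved; model checkpoints as a numpy archive with
the configuration embedded as YAML; traces and loss logs as CSV.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
import SimpleITK as sitk
import tifffile
import yaml

from .geometry import ProjectionSet, ScanGeometry, VolumeGrid

__all__ = ["write_geometry_sidecar", "read_geometry_sidecar",
           "write_projection_set", "read_projection_set",
           "write_volume", "read_volume", "write_loss_log",
           "write_trajectory_csv", "save_checkpoint", "load_checkpoint"]

_GEOM_FIELDS = ("sad", "sdd", "det_nu", "det_nv", "det_pitch_u", "det_pitch_v",
                "det_offset_u", "fan_mode")


def write_geometry_sidecar(geometry: ScanGeometry, path) -> None:
    doc = {k: getattr(geometry, k) for k in _GEOM_FIELDS}
    doc["n_frames"] = geometry.n_frames
    doc["angles_deg"] = [float(a) for a in geometry.angles]
    doc["timestamps_s"] = [float(t) for t in geometry.timestamps]
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_geometry_sidecar(path) -> ScanGeometry:
    doc = yaml.safe_load(Path(path).read_text())
    n = int(doc.pop("n_frames"))
    angles = np.asarray(doc.pop("angles_deg"), dtype=float)
    ts = np.asarray(doc.pop("timestamps_s"), dtype=float)
    if angles.size != n:
        raise ValueError(f"sidecar declares {n} frames but lists {angles.size} angles")
    return ScanGeometry(angles=angles, timestamps=ts, **doc)


def write_projection_set(projections: ProjectionSet, stack_path,
                         sidecar_path) -> None:
    """Write frames as multi-frame TIFF (.tif) or raw float32 (.raw)."""
    stack_path = Path(stack_path)
    frames = projections.frames.astype(np.float32)
    if stack_path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(stack_path, frames)
    elif stack_path.suffix.lower() == ".raw":
        frames.tofile(stack_path)
    else:
        raise ValueError(f"unsupported projection format {stack_path.suffix!r} "
                         "(use .tif/.tiff or .raw)")
    write_geometry_sidecar(projections.geometry, sidecar_path)


def read_projection_set(stack_path, sidecar_path) -> ProjectionSet:
    geometry = read_geometry_sidecar(sidecar_path)
    stack_path = Path(stack_path)
    if stack_path.suffix.lower() in (".tif", ".tiff"):
        frames = tifffile.imread(stack_path)
    elif stack_path.suffix.lower() == ".raw":
        frames = np.fromfile(stack_path, dtype=np.float32)
        expected = geometry.n_frames * geometry.det_nu * geometry.det_nv
        if frames.size != expected:
            raise ValueError(f"raw stack has {frames.size} values, sidecar "
                             f"implies {expected}")
        frames = frames.reshape(geometry.n_frames, geometry.det_nu, geometry.det_nv)
    else:
        raise ValueError(f"unsupported projection format {stack_path.suffix!r}")
    if frames.ndim == 2:
        frames = frames[None]
    if frames.shape[0] != geometry.n_frames:
        raise ValueError(f"stack has {frames.shape[0]} frames, sidecar declares "
                         f"{geometry.n_frames}")
    return ProjectionSet(np.asarray(frames, dtype=np.float64), geometry)


_VOLUME_SUFFIXES = (".nii", ".nii.gz", ".mha", ".mhd")


def _volume_suffix(path: Path) -> str:
    name = path.name.lower()
    for s in _VOLUME_SUFFIXES:
        if name.endswith(s):
            return s
    raise ValueError(f"unsupported volume format for {path.name!r}; "
                     f"supported: {', '.join(_VOLUME_SUFFIXES)}")


def write_volume(volume: VolumeGrid, path) -> None:
    """Write a volume as NIfTI (.nii/.nii.gz) or MetaImage (.mha/.mhd).

    The array is stored float32 with voxel size and origin preserved; the
    (x, y, z) array convention maps to the ITK (z, y, x) buffer order.
    """
    path = Path(path)
    _volume_suffix(path)
    img = sitk.GetImageFromArray(
        np.ascontiguousarray(volume.values.astype(np.float32).transpose(2, 1, 0)))
    img.SetSpacing(tuple(float(s) for s in volume.voxel_size))
    img.SetOrigin(tuple(float(o) for o in volume.origin))
    sitk.WriteImage(img, str(path))


def read_volume(path) -> VolumeGrid:
    path = Path(path)
    _volume_suffix(path)
    img = sitk.ReadImage(str(path))
    vals = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    return VolumeGrid(np.asarray(vals, dtype=np.float64),
                      np.asarray(img.GetSpacing()), np.asarray(img.GetOrigin()))


def write_loss_log(log: list[dict], path) -> None:
    pd.DataFrame(log).to_csv(path, index=False)


def write_trajectory_csv(times, angles, displacements, com, path) -> None:
    d = np.asarray(displacements)
    c = np.asarray(com)
    pd.DataFrame({
        "t_s": times, "angle_deg": angles,
        "dx_mm": d[:, 0], "dy_mm": d[:, 1], "dz_mm": d[:, 2],
        "com_x_mm": c[:, 0], "com_y_mm": c[:, 1], "com_z_mm": c[:, 2],
    }).to_csv(path, index=False)


def write_coefficients_csv(temporal, path, frames=None) -> None:
    w = temporal.coefficients_table(frames)
    cols = {"frame": np.arange(w.shape[0]) if frames is None else np.asarray(frames)}
    for i in range(3):
        for k, ax in enumerate("xyz"):
            cols[f"w{i + 1}{ax}"] = w[:, i, k]
    pd.DataFrame(cols).to_csv(path, index=False)


def save_checkpoint(path, model, config: dict | None = None) -> None:
    """Archive all learnable arrays plus the run configuration."""
    arrays = {"spatial.tables": model.spatial.encoder.tables.data}
    for li, (W, b) in enumerate(zip(model.spatial.mlp.weights,
                                    model.spatial.mlp.biases)):
        arrays[f"spatial.mlp.W{li}"] = W.data
        arrays[f"spatial.mlp.b{li}"] = b.data
    arrays["spatial.box_lo"] = model.spatial.box_lo
    arrays["spatial.box_hi"] = model.spatial.box_hi
    if model.temporal is not None:
        arrays["temporal.tables"] = model.temporal.encoder.tables.data
        for hi, head in enumerate(model.temporal.heads):
            for li, (W, b) in enumerate(zip(head.weights, head.biases)):
                arrays[f"temporal.h{hi}.W{li}"] = W.data
                arrays[f"temporal.h{hi}.b{li}"] = b.data
        arrays["temporal.n_frames"] = np.array(model.temporal.n_frames)
    if model.basis is not None:
        for gi, g in enumerate(model.basis.grids):
            arrays[f"mbc{gi}"] = g.control_values.data
    arrays["grid.voxel_size"] = model.grid.voxel_size
    arrays["grid.origin"] = model.grid.origin
    arrays["grid.dims"] = np.array(model.grid.dims)
    arrays["config_yaml"] = np.frombuffer(
        yaml.safe_dump(config or {}).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path):
    """Restore a DynamicModel (and its config dict) from an archive."""
    from .bspline import BSplineGrid, MotionBasisSet
    from .fields import SpatialField, TemporalField
    from .autodiff import Tensor
    from .encoding import HashEncoderConfig
    from .training import DynamicModel

    z = np.load(path)
    config = yaml.safe_load(bytes(z["config_yaml"]).decode()) or {}
    grid = VolumeGrid(np.zeros(tuple(z["grid.dims"])), z["grid.voxel_size"],
                      z["grid.origin"])

    tables = z["spatial.tables"]
    enc_cfg = HashEncoderConfig(**(config.get("spatial_encoder") or {}))
    spatial = SpatialField((z["spatial.box_lo"], z["spatial.box_hi"]),
                           encoder_config=enc_cfg)
    spatial.encoder.tables.data = tables
    for li in range(len(spatial.mlp.weights)):
        spatial.mlp.weights[li].data = z[f"spatial.mlp.W{li}"]
        spatial.mlp.biases[li].data = z[f"spatial.mlp.b{li}"]

    temporal = None
    if "temporal.tables" in z:
        t_cfg = HashEncoderConfig(**(config.get("temporal_encoder") or
                                     dict(levels=8, features_per_level=2,
                                          table_size=2**12, base_resolution=4,
                                          growth_factor=1.6, spatial_dim=1)))
        temporal = TemporalField(int(z["temporal.n_frames"]), encoder_config=t_cfg)
        temporal.encoder.tables.data = z["temporal.tables"]
        for hi, head in enumerate(temporal.heads):
            for li in range(len(head.weights)):
                head.weights[li].data = z[f"temporal.h{hi}.W{li}"]
                head.biases[li].data = z[f"temporal.h{hi}.b{li}"]

    basis = None
    if "mbc0" in z:
        grids = [BSplineGrid(gi + 1, Tensor(z[f"mbc{gi}"], requires_grad=True))
                 for gi in range(3)]
        basis = MotionBasisSet(grids)
    for p in spatial.parameters:
        p.requires_grad = True
    return DynamicModel(spatial, temporal, basis, grid), config
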