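"""Run configuration: one YAML document driving simulate/reconstruct/evaluate.

Unknown keys are rejected so typos fail loudly; the shipped defaults
regenerate the reduced X1-analog experiment end to end.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .encoding import HashEncoderConfig
from .geometry import ScanGeometry, VolumeGrid
from .phantom import MotionScenario, default_geometry
from .training import LossWeights, StageSchedule

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    """Everything needed to reproduce a run from the seed alone."""

    seed: int = 0
    # reconstruction grid (desk-scale X1-analog defaults)
    grid_dims: tuple[int, int, int] = (32, 32, 16)
    grid_voxel_mm: float = 12.0
    grid_center_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    # scan
    scan: dict = field(default_factory=lambda: dict(
        n_frames=110, duration_s=60.0, arc_deg=360.0, det_shape=(64, 32),
        det_pitch=9.0, sad=1000.0, sdd=1500.0, det_offset_u=0.0,
        fan_mode="full"))
    # simulator
    scenario_mode: str = "X1"
    noise_sigma: float = 0.0
    # model
    spatial_encoder: dict = field(default_factory=dict)
    temporal_encoder: dict = field(default_factory=dict)
    mbc_counts: tuple[int, int, int] = (5, 8, 12)
    omega0: float = 30.0
    # training
    schedule: dict = field(default_factory=lambda: dict(
        stage1_epochs=(40, 4), stage2_temporal_epochs=45,
        stage2_epochs_per_scale=2, stage2_finetune_epochs=2, stage3_epochs=4,
        rays_per_frame=512, tv_stride=2, chunk_frames=10))
    weights: dict = field(default_factory=lambda: dict(lambda_temporal=10.0))

    def make_grid(self) -> VolumeGrid:
        return VolumeGrid.empty(self.grid_dims, self.grid_voxel_mm,
                                center=self.grid_center_mm)

    def make_geometry(self) -> ScanGeometry:
        return default_geometry(**self.scan)

    def make_scenario(self) -> MotionScenario:
        return MotionScenario.preset(self.scenario_mode, seed=self.seed,
                                     duration_s=self.scan.get("duration_s", 60.0))

    def make_schedule(self) -> StageSchedule:
        return StageSchedule(seed=self.seed, **self.schedule)

    def make_weights(self) -> LossWeights:
        return LossWeights(**self.weights)

    def make_spatial_encoder(self) -> HashEncoderConfig:
        return HashEncoderConfig(**self.spatial_encoder) if self.spatial_encoder \
            else HashEncoderConfig(spatial_dim=3)

    def make_temporal_encoder(self) -> HashEncoderConfig | None:
        return HashEncoderConfig(**self.temporal_encoder) if self.temporal_encoder \
            else None

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path) -> RunConfig:
    doc = yaml.safe_load(Path(path).read_text()) or {}
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(doc) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key in ("grid_dims", "grid_center_mm", "mbc_counts"):
        if key in doc:
            doc[key] = tuple(doc[key])
    if "scan" in doc and "det_shape" in doc["scan"]:
        doc["scan"]["det_shape"] = tuple(doc["scan"]["det_shape"])
    return RunConfig(**doc)
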