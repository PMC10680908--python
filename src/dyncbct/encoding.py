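"""Multiresolution hash encoding of low-dimensional coordinates.

Each level overlays a uniform grid on the input domain; the grid vertices
surrounding a query are hashed into a per-level feature table and their
feature vectors are linearly (1D) or trilinearly (3D) interpolated.  Levels
of increasing resolution are concatenated.  Table entries are learnable;
the encoding is differentiable in both the tables and the query coordinates
(the latter is what lets motion parameters receive gradients through the
warped reference field).
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np

from .autodiff import Tensor

__all__ = ["HashEncoderConfig", "HashEncoder"]

@dataclass
class HashEncoderConfig:
    """Hyper-parameters of a multiresolution hash encoding."""

    levels: int = 8
    features_per_level: int = 2
    table_size: int = 2**16
    base_resolution: int = 8
    growth_factor: float = 1.5
    spatial_dim: int = 3

    def __post_init__(self):
        if self.levels < 1:
            raise ValueError("levels must be >= 1")
        if self.table_size & (self.table_size - 1):
            raise ValueError("table_size must be a power of two")
        if self.growth_factor <= 1.0:
            raise ValueError("growth_factor must exceed 1")
        if self.spatial_dim not in (1, 3):
            raise ValueError("spatial_dim must be 1 or 3")
        if len(set(self.resolutions())) != self.levels:
            raise ValueError("level resolutions must be strictly increasing")

    def resolutions(self) -> list[int]:
        return [int(np.floor(self.base_resolution * self.growth_factor**lv))
                for lv in range(self.levels)]

    @property
    def output_dim(self) -> int:
        return self.levels * self.features_per_level


class HashEncoder:
    """Learnable multiresolution hash encoding over [-1, 1]^d."""

    def __init__(self, config: HashEncoderConfig,
                 rng: np.random.Generator | None = None,
                 init_scale: float = 1e-2):
        rng = rng or np.random.default_rng()
        self.config = config
        self.tables = Tensor(
            rng.uniform(-init_scale, init_scale,
                        (config.levels, config.table_size, config.features_per_level)),
            requires_grad=True)

    @property
    def parameters(self) -> list[Tensor]:
        return [self.tables]

    def encode(self, coords) -> Tensor:
        """Encode coordinates in [-1, 1]^d -> features (M, levels * F).

        Coordinates marginally outside the domain are clamped; values farther
        than 1 + 1e-6 outside raise a domain error only when the input is a
        plain array (warped tensor inputs are clamped silently, since the
        motion model may transiently push samples out of the box).
        """
        from . import _kernels

        is_tensor = isinstance(coords, Tensor)
        c = coords.data if is_tensor else np.asarray(coords, dtype=np.float64)
        c = np.atleast_2d(c) if self.config.spatial_dim > 1 else np.reshape(c, (-1, 1))
        c = np.ascontiguousarray(c)
        if not is_tensor and np.any(np.abs(c) > 1.0 + 1e-6):
            raise ValueError("coordinates lie outside the [-1, 1] encoding domain")
        coords_t = coords if is_tensor else None

        cfg = self.config
        res = np.asarray(cfg.resolutions(), dtype=np.int64)
        tables = self.tables
        fw = _kernels.hash_encode3_fw if cfg.spatial_dim == 3 else \
            _kernels.hash_encode1_fw
        bwk = _kernels.hash_encode3_bw if cfg.spatial_dim == 3 else \
            _kernels.hash_encode1_bw
        out_data = fw(c, res, tables.data)

        def bw(g):
            need_gc = coords_t is not None and coords_t.requires_grad
            gtab, gc = bwk(c, res, tables.data, np.ascontiguousarray(g), need_gc)
            if tables.requires_grad:
                tables._accum(gtab)
            if need_gc:
                coords_t._accum(gc.reshape(coords_t.data.shape))

        parents = [tables] + ([coords_t] if coords_t is not None else [])
        if any(p.requires_grad for p in parents):
            return Tensor._node(out_data, tuple(parents), bw)
        return Tensor(out_data)
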