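"""Implicit neural fields: the reference volume and the temporal coefficients.

``SpatialField`` maps a 3D mm coordinate to a linear attenuation coefficient
(the reference volume of the dynamic sequence); ``TemporalField`` maps a frame
index to the 3 x 3 array of motion-basis coefficients w[i][k] (MBC index i,
Cartesian direction k).  Both consist of a multiresolution hash encoding
followed by small MLPs with periodic (SIREN) activations.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, as_tensor, concat, stack_last
from .encoding import HashEncoder, HashEncoderConfig
from .geometry import VolumeGrid

__all__ = ["SirenMLP", "SpatialField", "TemporalField"]


class SirenMLP:
    """A small fully connected network with sine activations.

    ``widths`` lists the layer output widths; all layers but the last apply
    ``sin(omega0 * z)``.  Initialization follows the standard SIREN scheme:
    first layer uniform in +/- 1/fan_in, later layers +/- sqrt(6/fan_in)/omega0.
    """

    def __init__(self, in_dim: int, widths: tuple[int, ...], omega0: float = 30.0,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.omega0 = omega0
        self.weights: list[Tensor] = []
        self.biases: list[Tensor] = []
        fan = in_dim
        for li, w in enumerate(widths):
            bound = 1.0 / fan if li == 0 else np.sqrt(6.0 / fan) / omega0
            self.weights.append(Tensor(rng.uniform(-bound, bound, (fan, w)),
                                       requires_grad=True))
            self.biases.append(Tensor(rng.uniform(-bound, bound, (w,)),
                                      requires_grad=True))
            fan = w

    @property
    def parameters(self) -> list[Tensor]:
        return self.weights + self.biases

    def __call__(self, x: Tensor) -> Tensor:
        h = x
        last = len(self.weights) - 1
        for li, (W, b) in enumerate(zip(self.weights, self.biases)):
            h = h @ W + b
            if li != last:
                h = (h * self.omega0).sin()
        return h


class SpatialField:
    """The reference-volume representation INR_spa.

    Hash-encodes a normalized 3D coordinate and maps the features through a
    three-layer SIREN MLP (widths 32, 32, 1) to an attenuation value in
    mm^-1.  ``domain_box`` is the (lo, hi) mm bounding box mapped onto
    [-1, 1]^3; points outside it evaluate to 0 (background).
    """

    def __init__(self, domain_box: tuple[np.ndarray, np.ndarray],
                 encoder_config: HashEncoderConfig | None = None,
                 omega0: float = 30.0, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        cfg = encoder_config or HashEncoderConfig(spatial_dim=3)
        if cfg.spatial_dim != 3:
            raise ValueError("spatial field needs a 3D encoder")
        self.encoder = HashEncoder(cfg, rng=rng)
        self.mlp = SirenMLP(cfg.output_dim, (32, 32, 1), omega0=omega0, rng=rng)
        self.box_lo = np.asarray(domain_box[0], dtype=float)
        self.box_hi = np.asarray(domain_box[1], dtype=float)

    @classmethod
    def for_volume(cls, volume: VolumeGrid, margin_mm: float = 0.0,
                   **kw) -> "SpatialField":
        lo, hi = volume.bounding_box
        half = volume.voxel_size / 2 + margin_mm
        return cls((lo - half, hi + half), **kw)

    @property
    def parameters(self) -> list[Tensor]:
        return self.encoder.parameters + self.mlp.parameters

    def normalize(self, points_mm) -> "Tensor | np.ndarray":
        center = (self.box_lo + self.box_hi) / 2.0
        half = (self.box_hi - self.box_lo) / 2.0
        if isinstance(points_mm, Tensor):
            return (points_mm - center) * (1.0 / half)
        return (np.asarray(points_mm, dtype=np.float64) - center) / half

    def __call__(self, points_mm) -> Tensor:
        """Attenuation at mm points (M, 3); differentiable in all parameters
        and, for Tensor input, in the points themselves."""
        data = points_mm.data if isinstance(points_mm, Tensor) else \
            np.asarray(points_mm, dtype=np.float64)
        if not np.all(np.isfinite(data)):
            raise ValueError("non-finite coordinates")
        c = self.normalize(points_mm)
        c_data = c.data if isinstance(c, Tensor) else c
        inside = np.all(np.abs(c_data) <= 1.0 + 1e-9, axis=-1).astype(float)
        if isinstance(c, Tensor):
            c = c.clip(-1.0, 1.0)
        else:
            c = np.clip(c, -1.0, 1.0)
        feats = self.encoder.encode(c)
        out = self.mlp(feats).reshape(-1)
        return out * inside

    def sample_volume(self, grid: VolumeGrid, batch: int = 65536,
                      clamp_negative: bool = True) -> VolumeGrid:
        """Evaluate the field at all voxel centers of ``grid`` (numpy only)."""
        pts = grid.voxel_centers()
        vals = np.empty(pts.shape[0])
        for s in range(0, pts.shape[0], batch):
            vals[s:s + batch] = self(pts[s:s + batch]).data
        if clamp_negative:
            np.maximum(vals, 0.0, out=vals)
        return grid.like(vals.reshape(grid.dims))


class TemporalField:
    """The temporal representation INR_tem.

    A 1D hash encoding of the (rescaled) frame index feeds nine SIREN MLPs,
    one per Cartesian component of each of the three MBCs; a full evaluation
    yields the 3 x 3 coefficient array w[i][k].  The representation is
    continuous in t, so non-integer frame indices are valid queries.
    """

    def __init__(self, n_frames: int,
                 encoder_config: HashEncoderConfig | None = None,
                 omega0: float = 30.0, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        cfg = encoder_config or HashEncoderConfig(
            levels=8, features_per_level=2, table_size=2**12,
            base_resolution=4, growth_factor=1.6, spatial_dim=1)
        if cfg.spatial_dim != 1:
            raise ValueError("temporal field needs a 1D encoder")
        self.encoder = HashEncoder(cfg, rng=rng)
        # nine heads: one input layer, two hidden layers, one output layer
        self.heads = [SirenMLP(cfg.output_dim, (32, 32, 32, 1), omega0=omega0,
                               rng=rng) for _ in range(9)]
        self.n_frames = int(n_frames)

    @property
    def parameters(self) -> list[Tensor]:
        params = list(self.encoder.parameters)
        for h in self.heads:
            params += h.parameters
        return params

    def normalize(self, t) -> np.ndarray:
        """Rescale frame index [0, n_frames - 1] -> [-1, 1]."""
        t = np.asarray(t, dtype=np.float64)
        if not np.all(np.isfinite(t)):
            raise ValueError("non-finite frame index")
        if self.n_frames > 1:
            return 2.0 * t / (self.n_frames - 1) - 1.0
        return np.zeros_like(t)

    def __call__(self, t) -> Tensor:
        """Coefficients at frame index/indices t -> Tensor (..., 3, 3)."""
        t = np.atleast_1d(np.asarray(t, dtype=np.float64))
        feats = self.encoder.encode(self.normalize(t).reshape(-1, 1))
        cols = [h(feats).reshape(-1) for h in self.heads]
        flat = stack_last(cols)  # (B, 9)
        out = flat.reshape(t.size, 3, 3)
        return out

    def coefficients_table(self, frames=None) -> np.ndarray:
        """Numpy (n, 3, 3) coefficient array over the given frame indices."""
        if frames is None:
            frames = np.arange(self.n_frames)
        return self(np.asarray(frames)).data
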