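"""Learnable cubic B-spline motion basis.

The deformation field at time t is a low-rank sum
``d(x, t) = sum_i w_i(t) * e_i(x)`` of L = 3 motion basis components (MBCs),
each a 3-vector field parametrized by a uniform grid of cubic B-spline
control points.  The three MBCs live on three grids of increasing resolution
so coarse bulk motion and fine local motion are represented at separate
scales.  Control values are learnable and dimensionless: basis fields are
expressed in normalized-box units (a displacement of 1 spans half the
reconstruction box), which makes the unit-norm orthonormality target and the
natural output scale of the temporal network mutually consistent; the warp
converts to mm.  Evaluation is separable (sequential 1D cubic
interpolations) and differentiable through the autodiff tape.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, stack_last

__all__ = [
    "bspline_basis_value",
    "uniform_cubic_weights",
    "BSplineGrid",
    "MotionBasisSet",
    "compose_dvf",
    "mbc_orthonormality_loss",
]


def bspline_basis_value(l: int, p: int, u: float, knots: np.ndarray) -> float:
    """Cox-de Boor recursion: value of basis B_{l,p} at u.

    Order 0 is the half-open indicator on [knots[l], knots[l+1]); 0/0 terms
    in the recursion are treated as 0.
    """
    if p < 0:
        raise ValueError("spline order must be >= 0")
    knots = np.asarray(knots, dtype=float)
    if np.any(np.diff(knots) < 0):
        raise ValueError("knot vector must be nondecreasing")
    if p == 0:
        return 1.0 if knots[l] <= u < knots[l + 1] else 0.0
    left_den = knots[l + p] - knots[l]
    right_den = knots[l + p + 1] - knots[l + 1]
    left = 0.0 if left_den == 0 else (u - knots[l]) / left_den * \
        bspline_basis_value(l, p - 1, u, knots)
    right = 0.0 if right_den == 0 else (knots[l + p + 1] - u) / right_den * \
        bspline_basis_value(l + 1, p - 1, u, knots)
    return left + right


def uniform_cubic_weights(f: np.ndarray) -> np.ndarray:
    """The four cubic B-spline blending weights at fractional position f.

    For a uniform knot vector, the value at a point falling a fraction
    ``f in [0, 1)`` into a knot span is ``sum_m w_m(f) P_{i+m}`` over the four
    supporting control points; these are the classic free-form-deformation
    weights, identical to Cox-de Boor on uniform knots.
    """
    f = np.asarray(f, dtype=np.float64)
    f2, f3 = f * f, f * f * f
    return np.stack([
        (1 - f) ** 3 / 6.0,
        (3 * f3 - 6 * f2 + 4) / 6.0,
        (-3 * f3 + 3 * f2 + 3 * f + 1) / 6.0,
        f3 / 6.0,
    ], axis=-1)


def _span_weights(q: np.ndarray, n_ctrl: int) -> tuple[np.ndarray, np.ndarray]:
    """Span start indices (M,) and blending weights (M, 4) along one axis.

    Queries are in [0, 1] (clamped); the grid has ``n_ctrl`` control points
    and ``n_ctrl - 3`` cubic spans covering the domain.
    """
    spans = n_ctrl - 3
    u = np.clip(q, 0.0, 1.0) * spans
    i = np.minimum(u.astype(np.int64), spans - 1)
    return i, uniform_cubic_weights(u - i)


@dataclass
class BSplineGrid:
    """One motion basis component: a uniform cubic B-spline vector field.

    ``control_values`` is a Tensor of shape (N, N, N, 3), dimensionless (box
    units); the field is evaluated over the normalized [0, 1]^3 box aligned
    to the reconstruction volume.
    """

    level: int
    control_values: Tensor

    def __post_init__(self):
        n = self.control_values.data.shape
        if len(n) != 4 or n[3] != 3 or n[0] != n[1] or n[0] != n[2]:
            raise ValueError("control_values must have shape (N, N, N, 3)")
        if n[0] < 4:
            raise ValueError("cubic interpolation needs at least 4 control points per axis")

    @property
    def n_ctrl(self) -> int:
        return self.control_values.data.shape[0]

    def evaluate(self, query: np.ndarray) -> Tensor:
        """e_i at query points (M, 3) in [0, 1]^3 -> Tensor (M, 3).

        Separable tensor-product evaluation; differentiable in the control
        values (the query points are treated as constants).
        """
        from . import _kernels

        query = np.ascontiguousarray(np.atleast_2d(np.asarray(query, dtype=np.float64)))
        ctrl = self.control_values
        out_data = _kernels.bspline3_fw(ctrl.data, query)

        def bw(g):
            gP = _kernels.bspline3_bw(self.n_ctrl, query, np.ascontiguousarray(g))
            ctrl._accum(gP)

        if ctrl.requires_grad:
            out = Tensor._node(out_data, (ctrl,), bw)
        else:
            out = Tensor(out_data)
        return out


@dataclass
class MotionBasisSet:
    """Three MBCs at three B-spline resolutions (coarse -> fine)."""

    grids: list[BSplineGrid]

    def __post_init__(self):
        if len(self.grids) != 3:
            raise ValueError("exactly 3 motion basis components are required")
        sizes = [g.n_ctrl for g in self.grids]
        if not all(a < b for a, b in zip(sizes, sizes[1:])):
            raise ValueError("MBC grid resolutions must strictly increase with level")

    # coarse -> fine initial axes: SI (dominant respiratory), AP, LR
    _INIT_AXES = (2, 1, 0)

    @classmethod
    def create(cls, control_counts=(6, 10, 17), init_std: float = 0.05,
               rng: np.random.Generator | None = None,
               init: str = "axis") -> "MotionBasisSet":
        """Create the basis set.

        ``init="axis"`` starts each component as a constant unit translation
        field along one Cartesian axis (plus N(0, init_std) jitter): the set
        is orthonormal from the start and the first coefficients to be
        learned correspond to rigid per-frame translations, which breaks the
        bilinear coefficient-times-field ambiguity of a cold start.
        ``init="random"`` uses pure N(0, init_std) fields.
        """
        rng = rng or np.random.default_rng()
        grids = []
        for lvl, n in enumerate(control_counts, start=1):
            vals = rng.normal(0.0, init_std, (n, n, n, 3))
            if init == "axis":
                vals[..., cls._INIT_AXES[lvl - 1]] += 1.0
            elif init != "random":
                raise ValueError(f"unknown init {init!r}")
            grids.append(BSplineGrid(lvl, Tensor(vals, requires_grad=True)))
        return cls(grids)

    @property
    def parameters(self) -> list[Tensor]:
        return [g.control_values for g in self.grids]

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters)

    def evaluate_all(self, query: np.ndarray) -> list[Tensor]:
        return [g.evaluate(query) for g in self.grids]


def compose_dvf(coeffs: Tensor, basis: MotionBasisSet, query: np.ndarray,
                mbc_values: list[Tensor] | None = None) -> Tensor:
    """DVF d(x, t) = sum_i w[i, k] * e_{i,k}(x) at the query points.

    ``coeffs`` is the (3, 3) temporal coefficient array (rows: MBC index i,
    columns: Cartesian direction k).  Precomputed ``mbc_values`` (as returned
    by ``MotionBasisSet.evaluate_all``) can be passed to avoid re-evaluating
    the basis.  Returns a Tensor (M, 3) of mm displacements, linear in the
    coefficients.
    """
    if not np.all(np.isfinite(coeffs.data)):
        raise ValueError("temporal coefficients must be finite")
    vals = mbc_values if mbc_values is not None else basis.evaluate_all(query)
    out = vals[0] * coeffs[0]
    for i in (1, 2):
        out = out + vals[i] * coeffs[i]
    return out


def mbc_orthonormality_loss(basis: MotionBasisSet,
                            quadrature_n: int = 16) -> Tensor:
    """Orthonormality penalty over the MBC set.

    ``sum_i | <e_i, e_i> - 1 | + sum_{i<j} | <e_i, e_j> |`` with the inner
    product discretized as the mean over a fixed uniform quadrature grid of
    the pointwise 3-vector dot products.  Zero iff the sampled fields are
    orthonormal.
    """
    if quadrature_n < 1:
        raise ValueError("quadrature grid must be nonempty")
    q = (np.arange(quadrature_n) + 0.5) / quadrature_n
    g = np.meshgrid(q, q, q, indexing="ij")
    pts = np.stack([a.ravel() for a in g], axis=-1)
    fields = basis.evaluate_all(pts)
    loss = None
    for i in range(3):
        for j in range(i, 3):
            ip = (fields[i] * fields[j]).sum(axis=1).mean()
            term = (ip - 1.0).abs() if i == j else ip.abs()
            loss = term if loss is None else loss + term
    return loss
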