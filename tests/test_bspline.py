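"""Cubic B-spline basis, motion basis components and DVF composition."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dyncbct.autodiff import Tensor
from dyncbct.bspline import (BSplineGrid, MotionBasisSet, bspline_basis_value,
                             compose_dvf, mbc_orthonormality_loss,
                             uniform_cubic_weights)


def brute_force_cox_de_boor(l, p, u, knots):
    """Independent textbook recursion (no shortcuts) used as the oracle."""
    if p == 0:
        return 1.0 if knots[l] <= u < knots[l + 1] else 0.0
    out = 0.0
    if knots[l + p] != knots[l]:
        out += (u - knots[l]) / (knots[l + p] - knots[l]) * \
            brute_force_cox_de_boor(l, p - 1, u, knots)
    if knots[l + p + 1] != knots[l + 1]:
        out += (knots[l + p + 1] - u) / (knots[l + p + 1] - knots[l + 1]) * \
            brute_force_cox_de_boor(l + 1, p - 1, u, knots)
    return out


class TestCoxDeBoor:
    def test_order_zero_indicator(self):
        knots = np.arange(6.0)
        assert bspline_basis_value(2, 0, 2.5, knots) == 1.0
        assert bspline_basis_value(2, 0, 3.0, knots) == 0.0  # half-open
        assert bspline_basis_value(2, 0, 1.9, knots) == 0.0

    def test_negative_order_rejected(self):
        with pytest.raises(ValueError):
            bspline_basis_value(0, -1, 0.5, np.arange(5.0))

    @given(st.floats(0.0, 0.999))
    @settings(max_examples=30, deadline=None)
    def test_matches_recursion_oracle(self, u):
        knots = np.arange(-3.0, 6.0)
        for l in range(5):
            ours = bspline_basis_value(l, 3, u, knots)
            oracle = brute_force_cox_de_boor(l, 3, u, knots)
            assert ours == pytest.approx(oracle, abs=1e-12)

    def test_cubic_values_at_integer_knots(self):
        # cardinal cubic B-spline on knots -3..1: 2/3 at its central knot -1,
        # 1/6 one knot to either side
        knots = np.arange(-3.0, 5.0)
        assert bspline_basis_value(0, 3, -2.0, knots) == pytest.approx(1 / 6, abs=1e-12)
        assert bspline_basis_value(0, 3, -1.0, knots) == pytest.approx(2 / 3, abs=1e-12)
        assert bspline_basis_value(0, 3, 0.0, knots) == pytest.approx(1 / 6, abs=1e-12)

    @given(st.floats(0.0, 1.0 - 1e-9))
    @settings(max_examples=30, deadline=None)
    def test_uniform_weights_equal_recursion(self, f):
        # the four blending weights are the cardinal basis values of the span
        knots = np.arange(-3.0, 6.0)
        w = uniform_cubic_weights(f)
        for m in range(4):
            # weight m multiplies control point i+m; with knots s_l = l - 3
            # that control's basis is B_{m,3} evaluated at the span fraction
            oracle = brute_force_cox_de_boor(m, 3, f, knots)
            assert w[m] == pytest.approx(oracle, abs=1e-12)

    @given(st.floats(0.0, 0.999))
    @settings(max_examples=30, deadline=None)
    def test_partition_of_unity(self, f):
        assert uniform_cubic_weights(f).sum() == pytest.approx(1.0, abs=1e-12)


class TestMbcField:
    def test_zero_controls_give_zero_field(self, rng):
        g = BSplineGrid(1, Tensor(np.zeros((5, 5, 5, 3))))
        out = g.evaluate(rng.uniform(0, 1, (50, 3)))
        np.testing.assert_allclose(out.data, 0.0)

    def test_constant_reproduction(self, rng):
        c = np.array([1.5, -2.0, 0.25])
        g = BSplineGrid(1, Tensor(np.broadcast_to(c, (6, 6, 6, 3)).copy()))
        out = g.evaluate(rng.uniform(0, 1, (100, 3)))
        np.testing.assert_allclose(out.data, np.broadcast_to(c, (100, 3)),
                                   atol=1e-12)

    def test_matches_dense_tensor_product_oracle(self, rng):
        n = 6
        P = rng.normal(size=(n, n, n, 3))
        g = BSplineGrid(1, Tensor(P))
        q = rng.uniform(0, 1, (100, 3))
        ours = g.evaluate(q).data
        # dense oracle: full Cox-de Boor sum over every control point
        spans = n - 3
        knots = np.arange(-3.0, n + 1.0) / spans  # uniform knots over [0, 1]
        oracle = np.zeros((100, 3))
        for m, (x, y, z) in enumerate(q):
            for lx in range(n):
                bx = brute_force_cox_de_boor(lx, 3, x, knots)
                if bx == 0.0:
                    continue
                for ly in range(n):
                    by = brute_force_cox_de_boor(ly, 3, y, knots)
                    if by == 0.0:
                        continue
                    for lz in range(n):
                        bz = brute_force_cox_de_boor(lz, 3, z, knots)
                        if bz:
                            oracle[m] += P[lx, ly, lz] * bx * by * bz
        np.testing.assert_allclose(ours, oracle, atol=1e-10)

    def test_c2_smoothness_across_knots(self):
        # second finite differences continuous across a knot joint
        rng = np.random.default_rng(7)
        g = BSplineGrid(1, Tensor(rng.normal(size=(8, 8, 8, 3))))
        knot_x = 1.0 / 5.0  # first interior knot (8 controls -> 5 spans)
        h = 1e-4
        xs = knot_x + np.array([-2 * h, -h, 0.0, h, 2 * h])
        q = np.stack([xs, np.full(5, 0.4), np.full(5, 0.6)], axis=1)
        vals = g.evaluate(q).data[:, 0]
        d2_left = (vals[0] - 2 * vals[1] + vals[2]) / h**2
        d2_right = (vals[2] - 2 * vals[3] + vals[4]) / h**2
        assert d2_left == pytest.approx(d2_right, abs=1e-2 * max(1, abs(d2_left)))

    def test_too_few_controls_rejected(self):
        with pytest.raises(ValueError):
            BSplineGrid(1, Tensor(np.zeros((3, 3, 3, 3))))


class TestComposeDvf:
    def test_zero_coefficients_zero_dvf(self, rng):
        basis = MotionBasisSet.create((4, 5, 6), rng=rng)
        d = compose_dvf(Tensor(np.zeros((3, 3))), basis, rng.uniform(0, 1, (20, 3)))
        np.testing.assert_allclose(d.data, 0.0)

    def test_basis_selection(self, rng):
        basis = MotionBasisSet.create((4, 5, 6), rng=rng)
        w = np.zeros((3, 3))
        w[0] = 1.0
        q = rng.uniform(0, 1, (20, 3))
        d = compose_dvf(Tensor(w), basis, q)
        np.testing.assert_allclose(d.data, basis.grids[0].evaluate(q).data,
                                   atol=1e-14)

    def test_linearity_in_coefficients(self, rng):
        basis = MotionBasisSet.create((4, 5, 6), rng=rng)
        q = rng.uniform(0, 1, (20, 3))
        w = rng.normal(size=(3, 3))
        alpha = 2.37
        d1 = compose_dvf(Tensor(alpha * w), basis, q).data
        d2 = alpha * compose_dvf(Tensor(w), basis, q).data
        np.testing.assert_allclose(d1, d2, atol=1e-12)
        # and the direct summation
        direct = sum(w[i][None, :] * basis.grids[i].evaluate(q).data
                     for i in range(3))
        np.testing.assert_allclose(compose_dvf(Tensor(w), basis, q).data,
                                   direct, atol=1e-12)

    def test_nonfinite_coefficients_rejected(self, rng):
        basis = MotionBasisSet.create((4, 5, 6), rng=rng)
        with pytest.raises(ValueError):
            compose_dvf(Tensor(np.full((3, 3), np.nan)), basis,
                        np.zeros((1, 3)))


class TestOrthonormalityLoss:
    def test_zero_fields_give_loss_three(self):
        grids = [BSplineGrid(i + 1, Tensor(np.zeros((n, n, n, 3))))
                 for i, n in enumerate((4, 5, 6))]
        loss = mbc_orthonormality_loss(MotionBasisSet(grids))
        assert loss.data == pytest.approx(3.0, abs=1e-12)

    def test_orthonormal_constant_fields_give_zero(self):
        # constant unit fields along x, y, z are orthonormal under the mean
        # inner product
        grids = []
        for i, n in enumerate((4, 5, 6)):
            P = np.zeros((n, n, n, 3))
            P[..., i] = 1.0
            grids.append(BSplineGrid(i + 1, Tensor(P)))
        loss = mbc_orthonormality_loss(MotionBasisSet(grids))
        assert loss.data == pytest.approx(0.0, abs=1e-10)

    def test_matches_dense_inner_product_oracle(self, rng):
        basis = MotionBasisSet.create((4, 5, 6), init_std=0.4, rng=rng)
        n = 8
        loss = mbc_orthonormality_loss(basis, quadrature_n=n)
        q = (np.arange(n) + 0.5) / n
        g = np.meshgrid(q, q, q, indexing="ij")
        pts = np.stack([a.ravel() for a in g], axis=-1)
        e = [basis.grids[i].evaluate(pts).data for i in range(3)]
        oracle = 0.0
        for i in range(3):
            oracle += abs((e[i] * e[i]).sum(axis=1).mean() - 1.0)
            for j in range(i + 1, 3):
                oracle += abs((e[i] * e[j]).sum(axis=1).mean())
        assert loss.data == pytest.approx(oracle, abs=1e-10)

    def test_empty_quadrature_rejected(self, rng):
        with pytest.raises(ValueError):
            mbc_orthonormality_loss(MotionBasisSet.create(rng=rng),
                                    quadrature_n=0)


def test_default_parameter_budget_is_order_1e4():
    basis = MotionBasisSet.create()
    assert 5e3 < basis.n_parameters() < 5e4
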