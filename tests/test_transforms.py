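import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spinereg.transforms import (
    AffineTransform,
    BSplineFFD,
    CompositeTransform,
    bspline_basis,
    bspline_basis_d1,
    load_transform,
    save_transform,
)


class TestBasis:
    def test_values_at_zero(self):
        np.testing.assert_allclose(bspline_basis(0.0), [1 / 6, 4 / 6, 1 / 6, 0])

    def test_values_at_half(self):
        np.testing.assert_allclose(
            bspline_basis(0.5), np.array([1, 23, 23, 1]) / 48.0
        )

    @given(st.floats(min_value=0.0, max_value=1.0, exclude_max=True))
    @settings(deadline=None)
    def test_partition_of_unity(self, u):
        assert bspline_basis(u).sum() == pytest.approx(1.0, abs=1e-12)

    @given(st.floats(min_value=0.0, max_value=1.0, exclude_max=True))
    @settings(deadline=None)
    def test_derivatives_sum_to_zero(self, u):
        assert bspline_basis_d1(u).sum() == pytest.approx(0.0, abs=1e-12)

    def test_domain_validation(self):
        with pytest.raises(ValueError):
            bspline_basis(1.0)
        with pytest.raises(ValueError):
            bspline_basis(-0.1)


class TestAffine:
    def test_identity(self):
        a = AffineTransform(c=(10, 20, 30))
        np.testing.assert_allclose(a.apply([[5, 5, 5]]), [[5, 5, 5]])

    def test_pure_translation(self):
        a = AffineTransform(t=(1, 2, 3))
        np.testing.assert_allclose(a.apply([[0, 0, 0]]), [[1, 2, 3]])

    def test_rotation_90_about_z(self):
        r = np.array([[0, -1, 0], [1, 0, 0], [0, 0, 1]], dtype=float)
        a = AffineTransform(R=r)
        np.testing.assert_allclose(a.apply([[1, 0, 0]]), [[0, 1, 0]], atol=1e-12)

    def test_center_invariance_of_identity(self, rng):
        for _ in range(5):
            c = rng.normal(0, 50, 3)
            a = AffineTransform(c=c)
            x = rng.normal(0, 20, (4, 3))
            np.testing.assert_allclose(a.apply(x), x, atol=1e-12)

    def test_inverse(self, rng):
        a = AffineTransform(R=np.eye(3) + rng.normal(0, 0.1, (3, 3)),
                            c=(3, 4, 5), t=rng.normal(0, 5, 3))
        x = rng.normal(0, 10, (6, 3))
        np.testing.assert_allclose(a.inverse().apply(a.apply(x)), x, atol=1e-9)

    def test_parameter_round_trip(self, rng):
        mu = rng.normal(0, 1, 12)
        mu[:9] += np.eye(3).ravel()  # keep R invertible
        a = AffineTransform()
        a.set_parameters(mu)
        np.testing.assert_array_equal(a.get_parameters(), mu)

    def test_identity_parameters_layout(self):
        np.testing.assert_array_equal(
            AffineTransform().get_parameters(),
            [1, 0, 0, 0, 1, 0, 0, 0, 1, 0, 0, 0],
        )

    def test_wrong_parameter_length(self):
        with pytest.raises(ValueError, match="12"):
            AffineTransform().set_parameters(np.zeros(10))

    def test_singular_matrix_rejected(self):
        with pytest.raises(ValueError):
            AffineTransform(R=np.zeros((3, 3)))


class TestFFD:
    def test_zero_field(self, rng):
        ffd = BSplineFFD((-20, -20, -20), (10, 10, 10), (8, 8, 8))
        pts = rng.uniform(0, 20, (30, 3))
        np.testing.assert_array_equal(ffd.displacement(pts), 0.0)

    def test_constant_coefficients_give_constant_displacement(self, rng):
        ffd = BSplineFFD((-20, -20, -20), (10, 10, 10), (8, 8, 8))
        ffd.coefficients[...] = [1.5, -2.0, 0.5]
        pts = rng.uniform(0, 25, (50, 3))
        np.testing.assert_allclose(ffd.displacement(pts),
                                   np.tile([1.5, -2.0, 0.5], (50, 1)), atol=1e-12)

    def test_local_support(self, rng):
        """Perturbing one control point changes nothing outside its 4-cell
        neighbourhood."""
        ffd = BSplineFFD((0, 0, 0), (10, 10, 10), (10, 10, 10))
        ffd.coefficients[5, 5, 5] = [3.0, 0, 0]
        # support of control point i: grid-local g in (i-2, i+2)
        pts_out = np.array([[25.0, 55.0, 55.0], [55.0, 25.0, 55.0],
                            [75.0, 55.0, 55.0], [55.0, 55.0, 75.0]])
        np.testing.assert_array_equal(ffd.displacement(pts_out), 0.0)
        pts_in = np.array([[50.0, 50.0, 50.0]])
        assert np.abs(ffd.displacement(pts_in)).max() > 0

    def test_outside_lattice_fails(self):
        ffd = BSplineFFD((0, 0, 0), (10, 10, 10), (6, 6, 6))
        with pytest.raises(ValueError, match="lattice"):
            ffd.displacement(np.array([[200.0, 0.0, 0.0]]))

    def test_second_derivatives_match_finite_differences(self, small_ffd):
        x = np.array([[12.3, 8.7, 15.1]])
        analytic = small_ffd.second_derivatives(x)[0]
        eps = 0.1
        fd = np.zeros((3, 3, 3))
        for a in range(3):
            for b in range(3):
                for s1 in (1, -1):
                    for s2 in (1, -1):
                        xp = x.copy()
                        xp[0, a] += s1 * eps
                        xp[0, b] += s2 * eps
                        fd[:, a, b] += s1 * s2 * small_ffd.displacement(xp)[0]
        fd /= 4 * eps * eps
        # agreement relative to the tensor's magnitude scale
        assert np.abs(analytic - fd).max() <= 1e-4 * np.abs(fd).max()

    def test_second_derivatives_symmetric(self, small_ffd, rng):
        pts = rng.uniform(0, 30, (20, 3))
        h = small_ffd.second_derivatives(pts)
        np.testing.assert_allclose(h, np.swapaxes(h, 2, 3), atol=1e-12)

    def test_constant_field_has_zero_second_derivatives(self):
        ffd = BSplineFFD((-20, -20, -20), (10, 10, 10), (8, 8, 8))
        ffd.coefficients[...] = [2.0, 1.0, -1.0]
        h = ffd.second_derivatives(np.array([[5.0, 5.0, 5.0]]))
        np.testing.assert_allclose(h, 0.0, atol=1e-12)

    def test_c1_continuity_across_knot(self, small_ffd):
        """First derivative continuous at a knot crossing (C2 spline)."""
        eps = 1e-6
        x0 = np.array([[10.0, 8.7, 15.1]])  # x = 10 crosses a knot plane
        left = (small_ffd.displacement(x0) - small_ffd.displacement(x0 - [[eps, 0, 0]])) / eps
        right = (small_ffd.displacement(x0 + [[eps, 0, 0]]) - small_ffd.displacement(x0)) / eps
        np.testing.assert_allclose(left, right, atol=1e-4)

    def test_jacobian_matches_finite_differences(self, small_ffd, rng):
        pts = rng.uniform(5, 25, (4, 3))
        jac = small_ffd.jacobian(pts)
        eps = 1e-4
        for n, x in enumerate(pts):
            for a in range(3):
                xp = x.copy(); xp[a] += eps
                xm = x.copy(); xm[a] -= eps
                fd = (small_ffd.apply(xp[None]) - small_ffd.apply(xm[None]))[0] / (2 * eps)
                np.testing.assert_allclose(jac[n, :, a], fd, atol=1e-6)

    def test_jacobian_identity_for_zero_field(self, rng):
        ffd = BSplineFFD((-20, -20, -20), (10, 10, 10), (8, 8, 8))
        jac = ffd.jacobian(rng.uniform(0, 20, (10, 3)))
        np.testing.assert_allclose(jac, np.tile(np.eye(3), (10, 1, 1)), atol=1e-14)

    def test_parameter_round_trip_and_length(self, rng):
        ffd = BSplineFFD((0, 0, 0), (10, 10, 10), (4, 4, 4))
        assert ffd.n_parameters == 192  # 3 * 4^3
        mu = rng.normal(0, 1, 192)
        ffd.set_parameters(mu)
        np.testing.assert_array_equal(ffd.get_parameters(), mu)

    def test_from_domain_covers_bbox(self, rng):
        lo, hi = np.array([0.0, 0, 0]), np.array([63.0, 63.0, 126.0])
        ffd = BSplineFFD.from_domain(lo, hi, 16.0)
        pts = rng.uniform(0, 1, (200, 3)) * (hi - lo) + lo
        assert ffd.covers(pts).all()
        ffd.displacement(pts)  # must not raise


class TestComposite:
    def test_zero_ffd_equals_affine(self, rng):
        aff = AffineTransform(t=(1, 2, 3))
        ffd = BSplineFFD.from_domain((0, 0, 0), (20, 20, 20), 10.0)
        comp = CompositeTransform(aff, ffd)
        pts = rng.uniform(0, 20, (10, 3))
        np.testing.assert_allclose(comp.apply(pts), aff.apply(pts))

    def test_translation_plus_constant_ffd(self, rng):
        aff = AffineTransform(t=(1, 0, 0))
        ffd = BSplineFFD.from_domain((0, 0, 0), (20, 20, 20), 10.0)
        ffd.coefficients[...] = [0, 2.0, 0]
        comp = CompositeTransform(aff, ffd)
        pts = rng.uniform(0, 20, (10, 3))
        np.testing.assert_allclose(comp.apply(pts), pts + [1.0, 2.0, 0.0],
                                   atol=1e-12)


class TestSerialization:
    @pytest.mark.parametrize("kind", ["affine", "ffd", "composite"])
    def test_round_trip(self, tmp_path, rng, kind):
        aff = AffineTransform(R=np.eye(3) + rng.normal(0, 0.05, (3, 3)),
                              c=(1, 2, 3), t=rng.normal(0, 3, 3))
        ffd = BSplineFFD.from_domain((0, 0, 0), (20, 20, 20), 8.0)
        ffd.coefficients = rng.normal(0, 1, ffd.coefficients.shape)
        obj = {"affine": aff, "ffd": ffd,
               "composite": CompositeTransform(aff, ffd)}[kind]
        path = str(tmp_path / "t.json")
        save_transform(obj, path)
        back = load_transform(path)
        pts = rng.uniform(0, 20, (20, 3))
        np.testing.assert_allclose(back.apply(pts), obj.apply(pts), atol=1e-12)
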