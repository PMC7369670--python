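import numpy as np
import pytest

from spinereg import metrics
from spinereg.transforms import AffineTransform, BSplineFFD, CompositeTransform
from spinereg.volumes import Volume


def dense_points(shape, step=1, offset=0.0):
    axes = [np.arange(0, n - 1, step) + offset for n in shape]
    g = np.meshgrid(*axes, indexing="ij")
    return np.stack([a.ravel() for a in g], axis=1)


class TestJointHistogram:
    def test_total_mass_one(self, rng):
        f = rng.uniform(0, 1, 500)
        m = rng.uniform(0, 1, 500)
        h = metrics.joint_histogram_from_values(f, m, 32, (0, 1), (0, 1))
        assert h.counts.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(h.counts >= 0)

    def test_identity_pair_concentrates_on_diagonal(self):
        rng = np.random.default_rng(0)
        # two-intensity phantom: diagonal joint structure
        data = (rng.uniform(0, 1, (16, 16, 16)) > 0.5).astype(float)
        v = Volume(data)
        pts = dense_points(v.shape, offset=0.25)
        h = metrics.estimate_joint_histogram(v, v, None, pts, bins=32,
                                             range_fixed=(0, 1), range_moving=(0, 1))
        # mass off the diagonal band (|bin_f - bin_m| > 3) below 5%
        nf, nm = h.counts.shape
        fi, mi = np.meshgrid(np.arange(nf), np.arange(nm) - 1, indexing="ij")
        off = np.abs(fi - mi) > 3
        assert h.counts[off].sum() < 0.05

    def test_independent_noise_factorises(self):
        rng = np.random.default_rng(1)
        n = 100_000
        f = rng.uniform(0, 1, n)
        m = rng.uniform(0, 1, n)
        h = metrics.joint_histogram_from_values(f, m, 16, (0, 1), (0, 1))
        pf, pm = h.marginals()
        np.testing.assert_allclose(h.counts, np.outer(pf, pm), atol=5e-4)

    def test_empty_overlap_fails(self, random_volume):
        t = AffineTransform(t=(1000.0, 0, 0))
        pts = dense_points(random_volume.shape)
        with pytest.raises(ValueError, match="empty overlap"):
            metrics.estimate_joint_histogram(random_volume, random_volume, t, pts)


class TestMutualInformation:
    def test_self_mi_equals_entropy(self, random_volume):
        pts = dense_points(random_volume.shape, offset=0.0)
        h = metrics.estimate_joint_histogram(random_volume, random_volume, None,
                                             pts, bins=32, kernel="discrete")
        pf, _ = h.marginals()
        hf = -np.sum(pf[pf > 0] * np.log(pf[pf > 0]))
        assert metrics.mutual_information(h) == pytest.approx(hf, rel=0.02)

    def test_independent_images_near_zero(self):
        rng = np.random.default_rng(2)
        n = 100_000
        h = metrics.joint_histogram_from_values(
            rng.uniform(0, 1, n), rng.uniform(0, 1, n), 16, (0, 1), (0, 1)
        )
        assert abs(metrics.mutual_information(h)) < 0.01

    def test_matches_brute_force_discrete_histogram(self):
        """Deterministic one-to-one intensity mapping: Parzen MI agrees with a
        plain discrete-histogram MI within 2%."""
        rng = np.random.default_rng(3)
        # 5 intensity levels on bin centres spaced wider than the cubic
        # kernel support, so each level's Parzen spread stays disjoint and
        # the spread entropy cancels between H(M) and H(F, M)
        levels = np.array([2, 9, 16, 23, 30]) / 31.0
        f = rng.choice(levels, size=20_000, p=(0.1, 0.15, 0.2, 0.25, 0.3))
        m = 1.0 - f  # bijective mapping between modalities
        h = metrics.joint_histogram_from_values(f, m, 32, (0.0, 1.0), (0.0, 1.0))
        mi = metrics.mutual_information(h)
        # brute-force oracle: discrete joint histogram over the 5 levels
        joint, _, _ = np.histogram2d(f, m, bins=5, range=[[0, 1.001], [0, 1.001]])
        p = joint / joint.sum()
        pf, pm = p.sum(1), p.sum(0)
        nz = p > 0
        mi_oracle = np.sum(p[nz] * np.log(p[nz] / np.outer(pf, pm)[nz]))
        assert mi == pytest.approx(mi_oracle, rel=0.02)


class TestNMI:
    def test_self_nmi_is_two(self, random_volume):
        pts = dense_points(random_volume.shape, offset=0.0)
        h = metrics.estimate_joint_histogram(random_volume, random_volume, None,
                                             pts, bins=32, kernel="discrete")
        assert metrics.normalized_mutual_information(h) == pytest.approx(2.0, abs=0.02)

    def test_independent_nmi_is_one(self):
        rng = np.random.default_rng(4)
        n = 100_000
        h = metrics.joint_histogram_from_values(
            rng.uniform(0, 1, n), rng.uniform(0, 1, n), 16, (0, 1), (0, 1)
        )
        assert metrics.normalized_mutual_information(h) == pytest.approx(1.0, abs=0.02)

    def test_invariant_under_affine_intensity_rescale(self, rng):
        f = rng.uniform(0, 1, 5000)
        m = np.sin(5 * f) + 0.1 * rng.normal(size=5000)
        h1 = metrics.joint_histogram_from_values(f, m, 32, (0, 1),
                                                 (m.min(), m.max()))
        f2, m2 = 3.0 * f - 1.0, -2.0 * m + 5.0
        h2 = metrics.joint_histogram_from_values(
            f2, m2, 32, (-1, 2), (m2.min(), m2.max())
        )
        # note: negative scaling reverses the moving axis; NMI is unchanged
        nmi1 = metrics.normalized_mutual_information(h1)
        nmi2 = metrics.normalized_mutual_information(h2)
        assert nmi1 == pytest.approx(nmi2, abs=1e-6)

    def test_degenerate_histogram_fails(self):
        h = metrics.joint_histogram_from_values(
            np.zeros(10), np.zeros(10), 8, (-0.5, 0.5), (-0.5, 0.5)
        )
        # all mass in one joint cell block: joint entropy may still be > 0
        # because the kernels spread mass; force a truly degenerate histogram
        h.counts = np.zeros_like(h.counts)
        h.counts[0, 0] = 1.0
        with pytest.raises(ValueError, match="degenerate"):
            metrics.normalized_mutual_information(h)

    def test_nmi_decreases_when_translated_out_of_alignment(self, smooth_pair):
        fixed, moving, rf, rm = smooth_pair
        pts = dense_points(fixed.shape, offset=0.4)
        vals = []
        for shift in np.linspace(0, 2.0, 10):
            t = AffineTransform(t=(shift, 0, 0))
            h = metrics.estimate_joint_histogram(
                fixed, fixed, t, pts, bins=16, range_fixed=rf, range_moving=rf
            )
            vals.append(metrics.normalized_mutual_information(h))
        # monotone decreasing trend (small tolerance for sampling effects)
        assert vals[0] == max(vals)
        assert vals[-1] < vals[0] - 0.05
        assert all(b <= a + 0.01 for a, b in zip(vals, vals[1:]))


class TestBendingEnergy:
    def test_zero_for_zero_and_constant_fields(self, rng):
        ffd = BSplineFFD((-20, -20, -20), (10, 10, 10), (8, 8, 8))
        pts = rng.uniform(0, 20, (50, 3))
        assert metrics.bending_energy(ffd, pts) == 0.0
        ffd.coefficients[...] = [4.0, -1.0, 2.0]
        assert metrics.bending_energy(ffd, pts) == pytest.approx(0.0, abs=1e-20)

    def test_quadratic_scaling(self, small_ffd, rng):
        pts = rng.uniform(0, 25, (60, 3))
        p1 = metrics.bending_energy(small_ffd, pts)
        scaled = BSplineFFD(small_ffd.grid_origin, small_ffd.grid_spacing,
                            small_ffd.grid_shape, 3.0 * small_ffd.coefficients)
        assert metrics.bending_energy(scaled, pts) == pytest.approx(9 * p1, rel=1e-9)

    def test_quadratic_displacement_closed_form(self, rng):
        """T_x = a x^2 has constant second derivative 2a, so P = (2a)^2."""
        a = 0.01
        ffd = BSplineFFD((-40, -40, -40), (10, 10, 10), (12, 12, 12))
        cp = ffd.control_point_positions().reshape(ffd.grid_shape + (3,))
        coef = np.zeros(ffd.grid_shape + (3,))
        coef[..., 0] = a * cp[..., 0] ** 2
        ffd.coefficients = coef
        pts = rng.uniform(0, 40, (500, 3))
        assert metrics.bending_energy(ffd, pts) == pytest.approx((2 * a) ** 2,
                                                                rel=0.01)

    def test_empty_point_set_fails(self, small_ffd):
        with pytest.raises(ValueError):
            metrics.bending_energy(small_ffd, np.zeros((0, 3)))

    def test_gradient_matches_finite_differences(self, small_ffd, rng):
        pts = rng.uniform(2, 28, (40, 3))
        value, grad = metrics.bending_energy_gradient(small_ffd, pts)
        mu0 = small_ffd.get_parameters()
        eps = 1e-5
        for i in rng.choice(mu0.size, 12, replace=False):
            mu = mu0.copy()
            mu[i] += eps
            small_ffd.set_parameters(mu)
            up = metrics.bending_energy(small_ffd, pts)
            mu[i] -= 2 * eps
            small_ffd.set_parameters(mu)
            dn = metrics.bending_energy(small_ffd, pts)
            small_ffd.set_parameters(mu0)
            assert grad[i] == pytest.approx((up - dn) / (2 * eps), rel=1e-5, abs=1e-10)


class TestCombinedCost:
    def test_self_alignment_cost_minus_two(self, random_volume):
        ffd = BSplineFFD.from_domain((0, 0, 0), (9, 9, 9), 5.0)
        comp = CompositeTransform(AffineTransform(), ffd)
        pts = dense_points(random_volume.shape, offset=0.0)
        terms = metrics.bep_nmi_cost(random_volume, random_volume, comp, pts,
                                     bins=32, kernel="discrete")
        assert terms.total == pytest.approx(-2.0, abs=0.02)
        assert terms.penalty == 0.0

    def test_gamma2_zero_reduces_to_minus_nmi(self, smooth_pair, dense_grid_points):
        fixed, moving, rf, rm = smooth_pair
        ffd = BSplineFFD.from_domain((0, 0, 0), (7, 7, 7), 3.0)
        rng = np.random.default_rng(0)
        ffd.coefficients = rng.normal(0, 0.2, ffd.coefficients.shape)
        comp = CompositeTransform(AffineTransform(), ffd)
        terms = metrics.bep_nmi_cost(fixed, moving, comp, dense_grid_points,
                                     bins=8, gamma2=0.0,
                                     range_fixed=rf, range_moving=rm)
        assert terms.total == -terms.nmi

    def test_penalty_scales_quadratically_with_warp_amplitude(self, rng):
        ffd = BSplineFFD((-20, -20, -20), (10, 10, 10), (8, 8, 8))
        base = rng.normal(0, 1, ffd.coefficients.shape)
        pts = rng.uniform(0, 20, (80, 3))
        ps = []
        for amp in (1.0, 2.0, 4.0):
            ffd.coefficients = amp * base
            ps.append(metrics.bending_energy(ffd, pts))
        assert ps[1] / ps[0] == pytest.approx(4.0, rel=0.02)
        assert ps[2] / ps[0] == pytest.approx(16.0, rel=0.02)


class TestCostGradient:
    """Analytic dC/dmu against central finite differences on a fixed dense
    sample set (well-conditioned 8^3 problem)."""

    def _fd_check(self, fixed, moving, transform, pts, rf, rm, eps, indices,
                  gamma2, tol):
        terms, grad = metrics.cost_and_gradient(
            fixed, moving, transform, pts, bins=8, gamma1=1.0, gamma2=gamma2,
            range_fixed=rf, range_moving=rm,
        )
        mu0 = transform.get_parameters()
        for i in indices:
            mu = mu0.copy()
            mu[i] += eps
            transform.set_parameters(mu)
            up = metrics.bep_nmi_cost(fixed, moving, transform, pts, bins=8,
                                      gamma2=gamma2, range_fixed=rf,
                                      range_moving=rm).total
            mu[i] -= 2 * eps
            transform.set_parameters(mu)
            dn = metrics.bep_nmi_cost(fixed, moving, transform, pts, bins=8,
                                      gamma2=gamma2, range_fixed=rf,
                                      range_moving=rm).total
            transform.set_parameters(mu0)
            fd = (up - dn) / (2 * eps)
            if abs(fd) > 1e-7:
                assert grad[i] == pytest.approx(fd, rel=tol)

    def test_affine_nmi_gradient(self, smooth_pair, dense_grid_points):
        fixed, moving, rf, rm = smooth_pair
        aff = AffineTransform(c=(3.5, 3.5, 3.5), t=(0.3, -0.2, 0.1))
        self._fd_check(fixed, moving, aff, dense_grid_points, rf, rm,
                       eps=1e-4, indices=range(12), gamma2=0.0, tol=1e-3)

    def test_ffd_bep_nmi_gradient(self, smooth_pair, dense_grid_points):
        fixed, moving, rf, rm = smooth_pair
        rng = np.random.default_rng(7)
        ffd = BSplineFFD.from_domain((0, 0, 0), (7, 7, 7), 3.0)
        ffd.coefficients = rng.normal(0, 0.2, ffd.coefficients.shape)
        comp = CompositeTransform(
            AffineTransform(c=(3.5, 3.5, 3.5), t=(0.3, -0.2, 0.1)), ffd
        )
        indices = rng.choice(comp.n_parameters, 40, replace=False)
        self._fd_check(fixed, moving, comp, dense_grid_points, rf, rm,
                       eps=3e-4, indices=indices, gamma2=1.0, tol=1e-3)

    def test_bep_only_gradient_zero_at_zero_coefficients(self, smooth_pair,
                                                         dense_grid_points):
        fixed, moving, rf, rm = smooth_pair
        ffd = BSplineFFD.from_domain((0, 0, 0), (7, 7, 7), 3.0)
        comp = CompositeTransform(AffineTransform(), ffd)
        terms, grad = metrics.cost_and_gradient(
            fixed, moving, comp, dense_grid_points, bins=8, gamma1=0.0,
            gamma2=1.0, range_fixed=rf, range_moving=rm,
        )
        np.testing.assert_allclose(grad, 0.0, atol=1e-15)
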