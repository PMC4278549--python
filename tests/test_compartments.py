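import numpy as np
import pytest

from mcdmri import compartments as cp
from mcdmri.pointsets import random_rotation, uniform_orientations
from tests.conftest import single_row_scheme

X = np.array([1.0, 0.0, 0.0])
Z = np.array([0.0, 0.0, 1.0])
D_PAR = 2e-9


class TestStickAndTensors:
    def test_stick_perpendicular_gradient_gives_one(self):
        sch = single_row_scheme(direction=(1, 0, 0))
        assert cp.stick_signal(sch, Z, D_PAR)[1] == pytest.approx(1.0)

    def test_stick_parallel_closed_form(self):
        # parallel gradient with b*d = 2 gives exp(-2) ~ 0.13534
        sch = single_row_scheme(direction=(1, 0, 0))
        d = 2.0 / sch.b[1]
        assert cp.stick_signal(sch, X, d)[1] == pytest.approx(np.exp(-2), rel=1e-12)

    def test_shell_average_at_least_parallel_signal(self, scheme):
        s = cp.stick_signal(scheme, X, D_PAR)
        rows = scheme.shell_rows(31)
        w = ~scheme.is_b0[rows]
        par = np.exp(-scheme.b[rows][w].max() * D_PAR)
        assert s[rows][w].mean() >= par

    def test_zeppelin_isotropic_limit_is_ball(self, scheme):
        z = cp.zeppelin_signal(scheme, X, 1.1e-9, 1.1e-9)
        b = cp.ball_signal(scheme, 1.1e-9)
        np.testing.assert_allclose(z, b, atol=1e-14)

    def test_ball_closed_form(self):
        # b = 1202 s/mm^2, d_iso = 0.7e-9: exp(-0.8414) ~ 0.4311
        sch = single_row_scheme(G=0.060, delta=10e-3, Delta=50e-3)
        assert round(sch.b_smm2[1]) == 1202
        val = cp.ball_signal(sch, 0.7e-9)[1]
        assert val == pytest.approx(np.exp(-sch.b[1] * 0.7e-9), rel=1e-12)
        assert val == pytest.approx(0.4311, abs=2e-4)

    def test_tensor_with_equal_minor_eigenvalues_is_zeppelin(self, scheme):
        rng = np.random.default_rng(0)
        for _ in range(10):
            th, ph, al = rng.uniform(0, np.pi, 3)
            z = cp.zeppelin_signal(scheme, cp.orientation_vector(th, ph), 2e-9, 0.7e-9)
            t = cp.tensor_signal(scheme, th, ph, al, 2e-9, 0.7e-9, 0.7e-9)
            assert np.abs(z - t).max() < 1e-12

    def test_tensor_eigenvalue_order_enforced(self, scheme):
        with pytest.raises(ValueError):
            cp.tensor_signal(scheme, 0.0, 0.0, 0.0, 1e-9, 2e-9, 0.5e-9)

    def test_rotational_equivariance(self, scheme):
        rng = np.random.default_rng(3)
        R = random_rotation(rng)
        n = cp.orientation_vector(1.1, 0.7)
        rot = type(scheme)(
            scheme.directions @ R.T, scheme.G, scheme.delta, scheme.Delta,
            scheme.shell_id, te=scheme.te,
        )
        for f in (
            lambda s, v: cp.stick_signal(s, v, D_PAR),
            lambda s, v: cp.zeppelin_signal(s, v, D_PAR, 0.7e-9),
            lambda s, v: cp.cylinder_signal(s, v, D_PAR, D_PAR, 2.5e-6),
        ):
            np.testing.assert_allclose(f(scheme, n), f(rot, R @ n), atol=1e-12)


class TestBesselRoots:
    def test_first_roots(self):
        assert cp.bessel_prime_roots("cylinder", 1)[0] == pytest.approx(1.84118, abs=1e-5)
        assert cp.bessel_prime_roots("sphere", 1)[0] == pytest.approx(2.08158, abs=1e-5)

    def test_asymptotic_spacing(self):
        for geom in ("cylinder", "sphere"):
            r = cp.bessel_prime_roots(geom, 30)
            gaps = np.diff(r)[-5:]
            np.testing.assert_allclose(gaps, np.pi, atol=5e-3)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            cp.bessel_prime_roots("cube", 3)
        with pytest.raises(ValueError):
            cp.bessel_prime_roots("cylinder", 0)


class TestCylinder:
    def test_zero_radius_limit_is_stick(self, scheme):
        c = cp.cylinder_signal(scheme, X, D_PAR, D_PAR, 1e-9)
        s = cp.stick_signal(scheme, X, D_PAR)
        assert np.abs(c - s).max() < 1e-6

    def test_parallel_gradient_is_free_diffusion(self):
        sch = single_row_scheme(direction=(1, 0, 0))
        c = cp.cylinder_signal(sch, X, D_PAR, D_PAR, 2.5e-6)
        assert c[1] == pytest.approx(np.exp(-sch.b[1] * D_PAR), rel=1e-10)

    def test_monotone_nonincreasing_in_radius(self):
        sch = single_row_scheme(direction=(1, 0, 0))
        vals = [cp.cylinder_signal(sch, Z, 0.0, D_PAR, R)[1] for R in
                (0.5e-6, 1e-6, 2e-6, 4e-6, 8e-6)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_series_converged_at_default_roots(self, scheme):
        a = cp.cylinder_signal(scheme, X, D_PAR, D_PAR, 2.5e-6, n_roots=20)
        b = cp.cylinder_signal(scheme, X, D_PAR, D_PAR, 2.5e-6, n_roots=40)
        assert np.abs(a - b).max() < 1e-8
        s1 = cp.sphere_signal(scheme, D_PAR, 2.5e-6, n_roots=20)
        s2 = cp.sphere_signal(scheme, D_PAR, 2.5e-6, n_roots=40)
        assert np.abs(s1 - s2).max() < 1e-8

    def test_invalid_radius(self, scheme):
        with pytest.raises(ValueError):
            cp.cylinder_signal(scheme, X, D_PAR, D_PAR, 0.0)


class TestGDRCylinders:
    def test_high_kappa_approaches_single_cylinder(self, scheme):
        # kappa*theta fixed at 2.5 um; higher kappa concentrates the Gamma
        # distribution about its mean so the mixture approaches one cylinder
        mean = 2.5e-6
        single = cp.cylinder_signal(scheme, X, D_PAR, D_PAR, mean)
        errs = []
        for kappa in (2.0, 5.0, 10.0):
            g = cp.gdr_cylinders_signal(scheme, X, D_PAR, D_PAR, kappa, mean / kappa)
            errs.append(np.abs(g - single).max())
        assert errs[0] > errs[1] > errs[2]
        assert errs[2] < 0.05

    def test_quadrature_refinement(self, scheme):
        a = cp.gdr_cylinders_signal(scheme, X, D_PAR, D_PAR, 2.0, 1.25e-6, n_nodes=16)
        b = cp.gdr_cylinders_signal(scheme, X, D_PAR, D_PAR, 2.0, 1.25e-6, n_nodes=64)
        assert np.abs(a - b).max() < 1e-4

    def test_weights_normalized(self):
        from mcdmri.compartments import _gamma_volume_quadrature

        for kappa, th in [(0.5, 2e-6), (2.0, 1e-6), (10.0, 0.25e-6)]:
            _, w = _gamma_volume_quadrature(kappa, th, 16)
            assert w.sum() == pytest.approx(1.0, abs=1e-12)

    def test_kappa_bounds_enforced(self, scheme):
        with pytest.raises(ValueError):
            cp.gdr_cylinders_signal(scheme, X, D_PAR, D_PAR, 11.0, 1e-6)
        with pytest.raises(ValueError):
            cp.gdr_cylinders_signal(scheme, X, D_PAR, D_PAR, 2.0, -1e-6)


class TestIsotropicCompartments:
    def test_dot_is_unity(self, scheme):
        assert np.all(cp.dot_signal(scheme) == 1.0)

    def test_astrosticks_closed_form(self):
        from scipy.special import erf

        sch = single_row_scheme()
        d = 2.0 / sch.b[1]  # b*d = 2
        expected = np.sqrt(np.pi) * erf(np.sqrt(2)) / (2 * np.sqrt(2))
        assert cp.astrosticks_signal(sch, d)[1] == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.5982, abs=1e-4)

    def test_astrosticks_matches_orientation_average_of_sticks(self, scheme):
        rng = np.random.default_rng(11)
        dirs = uniform_orientations(20000, rng)
        row = scheme.weighted.nonzero()[0][7]
        g = scheme.directions[row]
        bd = scheme.b[row] * D_PAR
        cos2 = (dirs @ g) ** 2
        brute = np.mean(np.exp(-bd * cos2))
        assert cp.astrosticks_signal(scheme, D_PAR)[row] == pytest.approx(brute, abs=2e-3)

    def test_sphere_zero_radius_limit_is_dot(self, scheme):
        s = cp.sphere_signal(scheme, D_PAR, 1e-9)
        assert np.abs(s - 1.0).max() < 1e-10

    def test_astrocylinders_small_radius_limit_is_astrosticks(self, scheme):
        ac = cp.astrocylinders_signal(scheme, D_PAR, 0.05e-6)
        ast = cp.astrosticks_signal(scheme, D_PAR)
        w = scheme.weighted
        assert np.abs(ac[w] / ast[w] - 1).max() < 1e-3

    def test_direction_independence_within_shells(self, scheme):
        # Astro*/Ball/Dot/Sphere depend on the shell, not the direction
        for sig in (
            cp.astrosticks_signal(scheme, D_PAR),
            cp.astrocylinders_signal(scheme, D_PAR, 1e-6),
            cp.sphere_signal(scheme, D_PAR, 2e-6),
            cp.ball_signal(scheme, 1e-9),
        ):
            for sid in (0, 31):
                rows = scheme.shell_rows(sid)
                vals = sig[rows][~scheme.is_b0[rows]]
                assert np.ptp(vals) < 1e-12

    def test_invalid_radius(self, scheme):
        with pytest.raises(ValueError):
            cp.sphere_signal(scheme, D_PAR, -1e-6)
        with pytest.raises(ValueError):
            cp.astrocylinders_signal(scheme, D_PAR, 0.0)


def test_all_compartments_unity_at_b0_and_in_unit_interval(scheme):
    signals = [
        cp.stick_signal(scheme, X, D_PAR),
        cp.zeppelin_signal(scheme, X, D_PAR, 0.7e-9),
        cp.tensor_signal(scheme, 1.0, 0.5, 0.2, 2e-9, 0.7e-9, 0.5e-9),
        cp.ball_signal(scheme, 1e-9),
        cp.cylinder_signal(scheme, X, D_PAR, D_PAR, 2.5e-6),
        cp.gdr_cylinders_signal(scheme, X, D_PAR, D_PAR, 2.0, 1e-6),
        cp.sphere_signal(scheme, D_PAR, 2e-6),
        cp.dot_signal(scheme),
        cp.astrosticks_signal(scheme, D_PAR),
        cp.astrocylinders_signal(scheme, D_PAR, 1e-6),
    ]
    for s in signals:
        assert np.all(s > 0) and np.all(s <= 1.0 + 1e-12)
        np.testing.assert_allclose(s[scheme.is_b0], 1.0, atol=1e-12)
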