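"""Closure correlations: deformation index, drag/lift coefficients and forces."""

import numpy as np
import pytest

from rbcdem.closures import (ClosureModel, LocalFlow, deformation_index,
                             dimensionless_state, drag_coefficient, drag_force,
                             lift_coefficient, lift_force, DI_FLOOR)


def poiseuille_flow(Re, r_star, R_c=25e-6, rho=1000.0, mu=1.2e-3, u_particle=None):
    """Local flow state of the analytic pipe Poiseuille profile at r = r* R_c."""
    nu = mu / rho
    u_max = Re * mu / (rho * 2 * R_c)
    r = r_star * R_c
    u_f = np.array([0.0, 0.0, u_max * (1 - r_star**2)])
    return LocalFlow(
        u_fluid=u_f,
        u_particle=u_f if u_particle is None else np.asarray(u_particle, float),
        shear_rate=2 * u_max * r / R_c**2,
        radial_unit=np.array([-1.0, 0.0, 0.0]),
        u_av=0.5 * u_max,
        nu=nu, rho=rho, d_p=5.6e-6, R_c=R_c,
    )


Z = np.array([0.0, 0.0, 1.0])


class TestDimensionlessState:
    @pytest.mark.parametrize("Re,r_star,expected", [
        (0.1, 0.2, 0.02),   # campaign grid minimum
        (0.5, 0.7, 0.35),   # campaign grid maximum
    ])
    def test_poiseuille_shear_mapping(self, Re, r_star, expected):
        s = dimensionless_state(poiseuille_flow(Re, r_star), Z)
        assert s.gamma_plus == pytest.approx(expected, rel=1e-12)

    def test_zero_relative_velocity(self):
        s = dimensionless_state(poiseuille_flow(0.3, 0.5), Z)
        assert s.u_r_plus == 0.0
        assert s.re_p == 0.0

    def test_u_r_plus_is_signed(self):
        flow = poiseuille_flow(0.3, 0.5)
        lag = flow.u_fluid - np.array([0, 0, 1e-4])
        s = dimensionless_state(poiseuille_flow(0.3, 0.5, u_particle=lag), Z)
        assert s.u_r_plus == pytest.approx(-1e-4 / flow.u_av)
        assert s.re_p == pytest.approx(5.6e-6 * 1e-4 / flow.nu)

    def test_zero_u_av_rejected(self):
        flow = poiseuille_flow(0.3, 0.5)
        bad = LocalFlow(flow.u_fluid, flow.u_particle, flow.shear_rate,
                        flow.radial_unit, 0.0, flow.nu, flow.rho, flow.d_p, flow.R_c)
        with pytest.raises(ValueError):
            dimensionless_state(bad, Z)


class TestDeformationIndex:
    def test_zero_shear_floors(self):
        from rbcdem.closures import DimensionlessState
        di = deformation_index(DimensionlessState(0.0, 0.0, 0.0))
        assert di == DI_FLOOR

    def test_hand_value_at_envelope_max(self):
        from rbcdem.closures import DimensionlessState
        di = deformation_index(DimensionlessState(0.35, 0.0, 0.0))
        assert di == pytest.approx(0.09939724121942738, rel=1e-12)

    def test_infinite_shear_asymptote(self):
        from rbcdem.closures import DimensionlessState
        di = deformation_index(DimensionlessState(1e9, 0.0, 0.0))
        assert di == pytest.approx(0.1, rel=1e-6)

    def test_monotone_in_gamma_plus(self):
        from rbcdem.closures import DimensionlessState
        g = np.linspace(0.0, 0.35, 400)
        di = np.array([deformation_index(DimensionlessState(x, 0.0, 0.0)) for x in g])
        assert np.all(np.diff(di) >= -1e-15)

    def test_bounded_on_declared_envelope(self):
        from rbcdem.closures import DimensionlessState
        rng = np.random.default_rng(42)
        for _ in range(500):
            g = rng.uniform(0.02, 0.35)
            u = rng.uniform(-1.0, 1.0)
            di = deformation_index(DimensionlessState(g, u, 0.05))
            assert 0.0 <= di < 1.0

    def test_out_of_envelope_warns_and_floors(self):
        from rbcdem.closures import DimensionlessState
        # large negative u_r+ makes the denominator negative
        with pytest.warns(RuntimeWarning):
            di = deformation_index(DimensionlessState(0.2, -3.0, 0.0))
        assert di == DI_FLOOR


class TestCoefficients:
    @pytest.mark.parametrize("DI,re_p,expected", [
        (0.0, 0.1, 1691.46),
        (0.1, 0.05, 3729.6800000000007),
    ])
    def test_drag_hand_values(self, DI, re_p, expected):
        assert drag_coefficient(DI, re_p) == pytest.approx(expected, rel=1e-12)

    def test_drag_identity(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            DI = rng.uniform(0.0, 0.99)
            re_p = rng.uniform(0.01, 0.12)
            c_d = drag_coefficient(DI, re_p)
            assert c_d * re_p**3 - 169.0 * re_p**2 * (DI + 1.0) == pytest.approx(0.00146, rel=1e-9)

    def test_drag_deformed_to_rigid_ratio(self):
        re_p = 1e4  # the (DI+1) factor dominates at large Re_p
        assert drag_coefficient(1.0, re_p) / drag_coefficient(0.0, re_p) == pytest.approx(2.0, rel=1e-6)

    def test_drag_raises_on_nonpositive(self):
        with pytest.raises(ValueError):
            drag_coefficient(0.1, 0.0)

    @pytest.mark.parametrize("DI,re_p,expected", [
        (0.1, 0.1, 2.55681),
        (1.0, 1.0, -0.7091999999999999),
    ])
    def test_lift_hand_values(self, DI, re_p, expected):
        assert lift_coefficient(DI, re_p) == pytest.approx(expected, rel=1e-12)

    def test_lift_zero_crossing_in_DI(self):
        # C_l(0.1, 1) > 0 and C_l(1, 1) < 0: a root lies between (bisection)
        lo, hi = 0.1, 1.0
        assert lift_coefficient(lo, 1.0) > 0 > lift_coefficient(hi, 1.0)
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if lift_coefficient(mid, 1.0) > 0:
                lo = mid
            else:
                hi = mid
        root = 0.5 * (lo + hi)
        assert 0.1 < root < 1.0
        assert lift_coefficient(root, 1.0) == pytest.approx(0.0, abs=1e-9)

    def test_lift_raises_unfloored(self):
        with pytest.raises(ValueError):
            lift_coefficient(0.0, 0.1)
        with pytest.raises(ValueError):
            lift_coefficient(0.1, 0.0)

    def test_constant_DI_leaves_re_p_dependence_only(self):
        # rigid-cell limit: freezing DI makes both coefficients functions of Re_p
        for re_p in (0.02, 0.05, 0.1):
            assert drag_coefficient(0.05, re_p) == drag_coefficient(0.05, re_p)
            c1 = lift_coefficient(0.05, re_p)
            c2 = lift_coefficient(0.05, re_p)
            assert c1 == c2


class TestForces:
    def test_drag_zero_at_zero_slip(self):
        flow = poiseuille_flow(0.3, 0.5)
        assert np.allclose(drag_force(flow, 100.0), 0.0)

    def test_drag_hand_value(self):
        u_f = np.array([1e-4, 0.0, 0.0])
        flow = LocalFlow(u_f, np.zeros(3), 0.0, np.array([0.0, 0.0, 0.0]),
                         1e-3, 1.2e-6, 1000.0, 7.82e-6, 25e-6)
        F = drag_force(flow, 1691.46)
        assert F[0] == pytest.approx(4.0619551494340026e-13, rel=1e-9)
        assert F[1] == F[2] == 0.0

    def test_drag_antiparallel_to_slip(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            u_f, u_p = rng.normal(size=3) * 1e-3, rng.normal(size=3) * 1e-3
            flow = LocalFlow(u_f, u_p, 10.0, np.array([0, 0, 0.0]),
                             1e-3, 1.2e-6, 1000.0, 5.6e-6, 25e-6)
            F = drag_force(flow, 50.0)
            cos = np.dot(F, u_p - u_f) / (np.linalg.norm(F) * np.linalg.norm(u_p - u_f))
            assert cos == pytest.approx(-1.0, abs=1e-12)

    def test_lift_zero_without_shear_and_slip(self):
        flow = poiseuille_flow(0.0, 0.0)
        assert np.allclose(lift_force(flow, 10.0), 0.0)

    def test_lift_hand_value(self):
        flow = LocalFlow(np.zeros(3), np.zeros(3), 100.0, np.array([-1.0, 0, 0]),
                         1e-3, 1.2e-6, 1000.0, 7.82e-6, 25e-6)
        F = lift_force(flow, 2.5568)
        assert np.linalg.norm(F) == pytest.approx(9.561450254663165e-14, rel=1e-9)
        assert F[0] < 0  # along radial_unit (centerward)

    def test_lift_d4_scaling(self):
        def mag(d_p):
            flow = LocalFlow(np.zeros(3), np.zeros(3), 200.0, np.array([-1.0, 0, 0]),
                             1e-3, 1.2e-6, 1000.0, d_p, 25e-6)
            return np.linalg.norm(lift_force(flow, 1.0))
        assert mag(2 * 5.6e-6) / mag(5.6e-6) == pytest.approx(16.0, rel=1e-12)

    def test_force_homogeneity(self):
        # drag is quadratic in the slip velocity, lift quadratic in shear
        def fd(scale):
            flow = LocalFlow(np.array([0, 0, scale * 1e-3]), np.zeros(3), 0.0,
                             np.zeros(3), 1e-3, 1.2e-6, 1000.0, 5.6e-6, 25e-6)
            return np.linalg.norm(drag_force(flow, 10.0))
        assert fd(3.0) / fd(1.0) == pytest.approx(9.0, rel=1e-12)

        def fl(scale):
            flow = LocalFlow(np.zeros(3), np.zeros(3), scale * 100.0,
                             np.array([-1, 0, 0.0]), 1e-3, 1.2e-6, 1000.0, 5.6e-6, 25e-6)
            return np.linalg.norm(lift_force(flow, 1.0))
        assert fl(3.0) / fl(1.0) == pytest.approx(9.0, rel=1e-12)


class TestClosureModel:
    def test_pipeline_centerward_lift_for_lagging_cell(self):
        flow = poiseuille_flow(0.5, 0.5)
        out = ClosureModel().evaluate(flow, Z)
        assert 0.09 < out.DI < 0.11
        assert out.C_d > 0
        assert out.C_l > 0  # dominant 2.48 DI / Re_p term: centerward migration

    def test_lift_disabled(self):
        flow = poiseuille_flow(0.5, 0.5)
        out = ClosureModel(lift_enabled=False).evaluate(flow, Z)
        assert out.C_l == 0.0
        assert np.allclose(out.F_lift, 0.0)

    def test_batch_matches_scalar_path(self):
        model = ClosureModel()
        # single Re so that every local flow shares the same bulk velocity
        flows = [poiseuille_flow(0.5, rs, u_particle=np.array([1e-5, 0, 1e-3 * k]))
                 for k in (-2, 0, 1) for rs in (0.2, 0.5, 0.7)]
        u_f = np.array([f.u_fluid for f in flows])
        u_p = np.array([f.u_particle for f in flows])
        shear = np.array([f.shear_rate for f in flows])
        rad = np.array([f.radial_unit for f in flows])
        di, c_d, c_l, f_d, f_l = model.evaluate_batch(
            u_f, u_p, shear, rad, Z, flows[0].u_av, flows[0].nu, flows[0].rho,
            5.6e-6, flows[0].R_c)
        for k, f in enumerate(flows):
            out = model.evaluate(f, Z)
            assert di[k] == pytest.approx(out.DI, rel=1e-12)
            assert c_d[k] == pytest.approx(out.C_d, rel=1e-12)
            assert c_l[k] == pytest.approx(out.C_l, rel=1e-12)
            assert np.allclose(f_d[k], out.F_drag, rtol=1e-12, atol=1e-25)
            assert np.allclose(f_l[k], out.F_lift, rtol=1e-12, atol=1e-25)
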