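"""Two-way coupling: void fraction, fluid forces, momentum exchange, full loop."""

import warnings

import numpy as np
import pytest

from rbcdem.coupling import (Simulation, assemble_Rpf, deposit_solid_fraction,
                             particle_fluid_force)
from rbcdem.dem import ContactParams, ParticleSet
from rbcdem.grid import FluidState, Grid
from rbcdem.scenarios import ChannelSpec, seed_particles, stenosis_case, straight_channel_case


def big_cell_grid():
    """Planar grid with cells much larger than a particle."""
    return Grid("planar", 8, 8, 50e-6, 50e-6)


class TestDeposition:
    def test_single_particle_single_cell_bookkeeping(self):
        grid = big_cell_grid()
        p = ParticleSet([[0.0, 125e-6, 125e-6]], d_p=5.6e-6)
        phi, solid = deposit_solid_fraction(p, grid, smoothing=0)
        i, j = 2, 2
        assert solid[i, j] == pytest.approx(np.pi * (5.6e-6) ** 3 / 6, rel=1e-12)
        assert ((1.0 - phi) * grid.V_cell)[i, j] == pytest.approx(np.pi * (5.6e-6) ** 3 / 6, rel=1e-9)
        assert solid.sum() == pytest.approx(solid[i, j], rel=1e-12)

    def test_no_particles_gives_unity(self):
        grid = big_cell_grid()
        phi, solid = deposit_solid_fraction(ParticleSet(np.zeros((0, 3))), grid)
        assert np.all(phi == 1.0)
        assert np.all(solid == 0.0)

    def test_global_volume_conservation(self):
        spec = ChannelSpec(R_c=25e-6, L=200e-6, Re=0.5, Ht_c=0.03)
        pos = seed_particles(spec, seed=4)
        p = ParticleSet(pos, d_p=5.6e-6)
        from rbcdem.grid import build_grid
        grid = build_grid(spec, (16, 32))
        for smoothing in (0, 1, 2):
            _, solid = deposit_solid_fraction(p, grid, smoothing=smoothing)
            expected = len(p) * np.pi * (5.6e-6) ** 3 / 6
            assert solid.sum() == pytest.approx(expected, rel=1e-10)


class TestParticleFluidForce:
    def test_uniform_flow_zero_total(self):
        ff = particle_fluid_force(1e-16, np.zeros(3), np.zeros(3), 1.2e-3,
                                  np.zeros(3), np.zeros(3))
        assert np.allclose(ff.total, 0.0)

    def test_pressure_force_exact(self):
        grad_p = np.array([0.0, 0.0, 1e4])
        v_p = np.pi * (5.6e-6) ** 3 / 6
        ff = particle_fluid_force(v_p, grad_p, np.zeros(3), 1.2e-3, np.zeros(3), np.zeros(3))
        assert np.allclose(ff.pressure[0], -v_p * grad_p)
        assert np.allclose(ff.total[0], -v_p * grad_p)

    def test_stationary_particle_in_poiseuille(self):
        # drag along the flow, lift centerward for a held particle at r* = 0.5
        from rbcdem.closures import ClosureModel, LocalFlow
        spec = ChannelSpec(R_c=25e-6, L=100e-6, Re=0.5)
        r = 12.5e-6
        u_f = np.array([0, 0, spec.u_max * (1 - 0.25)])
        flow = LocalFlow(u_fluid=u_f, u_particle=np.zeros(3),
                         shear_rate=2 * spec.u_max * r / spec.R_c**2,
                         radial_unit=np.array([-1.0, 0, 0]), u_av=spec.u_av,
                         nu=spec.nu, rho=spec.rho, d_p=5.6e-6, R_c=spec.R_c)
        out = ClosureModel().evaluate(flow, np.array([0, 0, 1.0]))
        assert out.F_drag[2] > 0          # along the flow
        assert out.F_lift[0] < 0          # toward the axis (particle on +x)


class TestAssembleRpf:
    def test_no_particles_zero_field(self):
        grid = big_cell_grid()
        st = FluidState.quiescent(grid)
        f = assemble_Rpf(ParticleSet(np.zeros((0, 3))), grid, st)
        assert np.all(f.K == 0.0)
        assert np.all(f.up_mean == 0.0)

    def test_single_particle_identity(self):
        # Eq-level identity: K |u - <u_p>| V_cell = |F_drag + F_lift|
        grid = big_cell_grid()
        st = FluidState.quiescent(grid)
        st.u_z[:] = 2e-3
        p = ParticleSet([[0.0, 125e-6, 125e-6]], d_p=5.6e-6)
        p.vel[0] = (0.0, 0.0, 5e-4)
        p.F_drag[0] = (0.0, 0.0, 3e-11)
        p.F_lift[0] = (0.0, 1e-12, 0.0)
        f = assemble_Rpf(p, grid, st)
        i, j = 2, 2
        u_c = np.array([2e-3, 0.0])                      # (z, r) components
        up = np.array([5e-4, 0.0])
        slip = np.linalg.norm(u_c - up)
        F = np.linalg.norm(p.F_drag[0] + p.F_lift[0])
        assert f.K[i, j] * slip * grid.V_cell[i, j] == pytest.approx(F, rel=1e-9)

    def test_two_particle_volume_weighted_mean(self):
        grid = big_cell_grid()
        st = FluidState.quiescent(grid)
        d1, d2 = 5.6e-6, 4.0e-6
        p = ParticleSet([[0.0, 125e-6, 120e-6], [0.0, 125e-6, 130e-6]], d_p=[d1, d2])
        p.vel[0, 2] = 1e-3
        p.vel[1, 2] = -2e-3
        f = assemble_Rpf(p, grid, st)
        v1, v2 = np.pi * d1**3 / 6, np.pi * d2**3 / 6
        expected = (v1 * 1e-3 + v2 * -2e-3) / (v1 + v2)
        assert f.up_mean[2, 2, 0] == pytest.approx(expected, rel=1e-9)


class TestCoupledRuns:
    def test_zero_particles_reduces_to_poiseuille(self):
        cfg = straight_channel_case(D=50e-6, L=100e-6, Re=0.5, Ht_c=0.0, seed=0)
        sim = Simulation(cfg)
        for _ in range(20):
            sim.step()
        spec = cfg.channel
        exact = spec.body_force * (spec.R_c**2 - sim.grid.r_c**2) / (4 * spec.mu)
        assert np.abs(sim.fluid.u_z - exact[:, None]).max() / exact.max() < 1e-6
        df = sim.samples
        assert np.all(df.Q_RBCs == 0.0)
        assert spec.plasma_flux / df.Q_blood.mean() == pytest.approx(1.0, abs=2e-3)

    def test_determinism_bit_identical(self):
        cfg = straight_channel_case(D=50e-6, L=100e-6, Re=0.5, Ht_c=0.03, seed=11)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a, b = Simulation(cfg), Simulation(cfg)
            for _ in range(25):
                a.step()
                b.step()
        assert np.array_equal(a.particles.pos, b.particles.pos)
        assert np.array_equal(a.particles.vel, b.particles.vel)
        assert np.array_equal(a.fluid.u_z, b.fluid.u_z)

    def test_momentum_audit_one_step(self):
        # held particle with a maintained axial lag (the resolved-campaign
        # configuration): after the deposition field settles, the fluid
        # momentum removed by R_pf matches the drag impulse within 1%
        cfg = straight_channel_case(D=50e-6, L=100e-6, Re=0.5, Ht_c=0.0, seed=0,
                                    contacts=ContactParams(young=1e6),
                                    lift_enabled=False, n_coupling=10)
        sim = Simulation(cfg)
        p = ParticleSet([[12.5e-6, 0.0, 50e-6]], d_p=cfg.d_p, rho_p=cfg.rho_p)
        sim.particles = p
        from rbcdem.grid import sample_fields
        home = p.pos.copy()
        audit = None
        for _ in range(15):
            p.pos[:] = home
            u_f = sample_fields(sim.fluid, sim.grid, p.pos)["u"]
            p.vel = u_f - np.array([[0.0, 0.0, 1e-4]])
            audit = sim.step(audit=True)
        assert audit["particle_impulse_z"] > 0  # drag pulls the lagging cell forward
        assert audit["fluid_momentum_removed_z"] == pytest.approx(
            audit["particle_impulse_z"], rel=0.01)

    def test_single_particle_migrates_centerward_only_with_lift(self):
        def radial_drift(lift_enabled):
            cfg = straight_channel_case(D=50e-6, L=100e-6, Re=0.5, Ht_c=0.0, seed=0,
                                        lift_enabled=lift_enabled)
            sim = Simulation(cfg)
            p = ParticleSet([[12.5e-6, 0.0, 50e-6]], d_p=cfg.d_p, rho_p=cfg.rho_p)
            from rbcdem.grid import sample_fields
            p.vel = sample_fields(sim.fluid, sim.grid, p.pos)["u"].copy()
            sim.particles = p
            radii = []
            for k in range(240):
                sim.step()
                if k % 40 == 0:
                    radii.append(np.hypot(p.pos[0, 0], p.pos[0, 1]))
            radii.append(np.hypot(p.pos[0, 0], p.pos[0, 1]))
            return np.array(radii)

        with_lift = radial_drift(True)
        assert np.all(np.diff(with_lift) < 0)            # monotone centerward
        assert with_lift[0] - with_lift[-1] > 2e-7       # measurable migration
        without_lift = radial_drift(False)
        assert abs(without_lift[0] - without_lift[-1]) < 0.1 * (with_lift[0] - with_lift[-1])

    def test_stenosis_deformation_peaks_in_throat(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            spec = stenosis_case(D=50e-6, throat=25e-6, L=200e-6, Re=0.5, Ht_c=0.03)
            from rbcdem.scenarios import CaseConfig
            cfg = CaseConfig(channel=spec, contacts=ContactParams(young=100.0), seed=2)
            sim = Simulation(cfg)
            for _ in range(120):
                sim.step()
        from rbcdem.metrics import di_statistics
        out = di_statistics(sim.particles, n_stream_bins=8, L=spec.L)
        prof = out["stream_profile"]
        throat = np.nanmean(prof[3:5])     # constriction is centred at L/2
        upstream = np.nanmean(prof[0:2])
        assert throat > upstream
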