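"""Case generation: campaign grid, particle seeding, stenosis/bifurcation geometry."""

import numpy as np
import pytest

from rbcdem.scenarios import (CaseConfig, ChannelSpec, bifurcation_case, campaign_grid,
                              seed_particles, stenosis_case, straight_channel_case)


class TestCampaignGrid:
    def test_grid_size(self):
        assert len(campaign_grid()) == 30  # six positions x five Reynolds numbers

    def test_dimensionless_shear_range(self):
        g = [p.gamma_plus for p in campaign_grid()]
        assert min(g) == pytest.approx(0.02, rel=1e-12)
        assert max(g) == pytest.approx(0.35, rel=1e-12)

    def test_reduction_matches_Re_rstar(self):
        for p in campaign_grid():
            assert p.gamma_plus == pytest.approx(p.Re * p.r_star, rel=1e-12)

    def test_agrees_with_finite_difference_shear(self):
        # independent check: gamma from a centred difference of the Poiseuille profile
        R_c, rho, mu = 25e-6, 1000.0, 1.2e-3
        nu = mu / rho
        for p in campaign_grid(R_c=R_c, rho=rho, mu=mu):
            u_max = p.Re * mu / (rho * 2 * R_c)
            u = lambda r: u_max * (1 - (r / R_c) ** 2)
            h = 1e-9
            r = p.r_star * R_c
            shear_fd = abs(u(r + h) - u(r - h)) / (2 * h)
            assert p.gamma_plus == pytest.approx(shear_fd * R_c**2 / nu, rel=1e-6)


class TestSeeding:
    def spec(self, ht=0.05):
        return ChannelSpec(R_c=25e-6, L=200e-6, Re=0.5, Ht_c=ht)

    def test_zero_hematocrit_empty(self):
        assert seed_particles(self.spec(0.0)).shape == (0, 3)

    def test_particle_count_from_volume_bookkeeping(self):
        spec = self.spec(0.05)
        d_p = 5.6e-6
        pos = seed_particles(spec, d_p=d_p, seed=0)
        expected = round(0.05 * np.pi * (25e-6) ** 2 * 200e-6 / (np.pi * d_p**3 / 6))
        assert len(pos) == expected

    def test_determinism(self):
        spec = self.spec()
        a = seed_particles(spec, seed=123)
        b = seed_particles(spec, seed=123)
        assert np.array_equal(a, b)
        c = seed_particles(spec, seed=124)
        assert not np.array_equal(a, c)

    def test_no_overlaps_and_wall_clearance(self):
        spec = self.spec()
        d_p = 5.6e-6
        pos = seed_particles(spec, d_p=d_p, seed=7)
        r = np.hypot(pos[:, 0], pos[:, 1])
        assert np.all(r <= spec.R_c - 0.5 * d_p + 1e-12)
        from scipy.spatial import cKDTree
        dmin = cKDTree(pos).query(pos, k=2)[0][:, 1]
        assert dmin.min() >= d_p - 1e-12

    def test_achieved_fraction_across_seeds(self):
        spec = self.spec(0.05)
        d_p = 5.6e-6
        v_chan = np.pi * spec.R_c**2 * spec.L
        for seed in range(10):
            pos = seed_particles(spec, d_p=d_p, seed=seed)
            ht = len(pos) * np.pi * d_p**3 / 6 / v_chan
            assert abs(ht - 0.05) / 0.05 < 0.02

    def test_exhausted_rejection_budget_raises(self):
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            spec = ChannelSpec(R_c=25e-6, L=200e-6, Re=0.1, Ht_c=0.15)
        with pytest.raises(RuntimeError, match="budget"):
            # budget barely above the particle count cannot absorb rejections
            seed_particles(spec, d_p=5.6e-6, seed=0, max_tries=660)


class TestChannelSpec:
    def test_hematocrit_bounds(self):
        with pytest.raises(ValueError):
            ChannelSpec(R_c=25e-6, L=100e-6, Re=0.1, Ht_c=0.2)
        with pytest.warns(RuntimeWarning):
            ChannelSpec(R_c=25e-6, L=100e-6, Re=0.1, Ht_c=0.10)

    def test_poiseuille_quantities(self):
        spec = ChannelSpec(R_c=25e-6, L=100e-6, Re=0.5)
        # Re = rho D U_max / mu
        assert spec.rho * spec.D * spec.u_max / spec.mu == pytest.approx(0.5)
        # driving force reproduces u_max at the axis
        assert spec.body_force * spec.R_c**2 / (4 * spec.mu) == pytest.approx(spec.u_max)
        assert spec.plasma_flux == pytest.approx(np.pi * spec.body_force * spec.R_c**4 / (8 * spec.mu))


class TestStenosis:
    def test_full_throat_is_straight(self):
        spec = stenosis_case(D=150e-6, throat=150e-6)
        assert spec.stenosis is None
        z = np.linspace(0, spec.L, 100)
        assert np.all(spec.wall_radius(z) == spec.R_c)

    def test_throat_open_fraction(self):
        spec = stenosis_case(D=150e-6, throat=85e-6)
        r_throat = spec.wall_radius(np.array([0.5 * spec.L]))[0]
        assert r_throat / spec.R_c == pytest.approx(85.0 / 150.0, rel=1e-12)

    def test_mask_excluded_from_grid_volume(self):
        from rbcdem.grid import build_grid
        spec = stenosis_case(D=50e-6, throat=25e-6, L=200e-6, Ht_c=0.0)
        grid = build_grid(spec, (16, 32))
        assert grid.solid_mask.any()
        full = np.pi * spec.R_c**2 * spec.L
        assert grid.total_fluid_volume() < full

    def test_throat_larger_than_diameter_rejected(self):
        with pytest.raises(ValueError):
            stenosis_case(D=50e-6, throat=60e-6)


class TestBifurcation:
    def test_orthogonal_daughter_at_90_degrees(self):
        case = bifurcation_case(90.0)
        d = case.daughter_direction
        assert np.dot(d, np.array([1.0, 0.0])) == pytest.approx(0.0, abs=1e-12)

    def test_angle_bounds(self):
        with pytest.raises(ValueError):
            bifurcation_case(0.0)
        with pytest.raises(ValueError):
            bifurcation_case(120.0)

    def test_mask_contains_both_branches(self):
        case = bifurcation_case(60.0)
        H, L = case.domain_size
        y = np.linspace(0, H, 96)
        z = np.linspace(0, L, 128)
        solid = case.solid_mask(y, z)
        # a point on the parent centreline upstream is open
        jy = np.argmin(np.abs(y - 0.5 * case.width))
        jz = np.argmin(np.abs(z - 0.5 * case.parent_length))
        assert not solid[jy, jz]
        # a point along the daughter centreline is open
        c = case.junction + 150e-6 * case.daughter_direction
        assert not solid[np.argmin(np.abs(y - c[1])), np.argmin(np.abs(z - c[0]))]
        # far corner is blocked
        assert solid[-1, 0]

    def test_cuts_at_200um(self):
        case = bifurcation_case(45.0)
        cuts = case.cuts
        for cut in cuts.values():
            d = np.hypot(cut.center[0] - case.junction[0], cut.center[1] - case.junction[1])
            assert d == pytest.approx(200e-6, rel=1e-12)


class TestCaseConfig:
    def test_yaml_roundtrip(self, tmp_path):
        cfg = straight_channel_case(D=50e-6, L=200e-6, Re=0.5, Ht_c=0.05, seed=3)
        path = tmp_path / "case.yaml"
        cfg.to_yaml(path)
        back = CaseConfig.from_yaml(path)
        assert back.channel == cfg.channel
        assert back.contacts == cfg.contacts
        assert back.seed == 3
        assert back.resolution == cfg.resolution
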