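"""Lattice Boltzmann flow solver vs analytic oracles."""

import numpy as np
import pytest

from thrombosim import flow as fl
from thrombosim import geometry as geo

FAST = dict(convergence_tol=1e-5, check_every=100)


@pytest.fixture(scope="module")
def tube_solution():
    """Poiseuille tube d=40 um at 16 voxels/diameter, wall shear 500 1/s."""
    dom = geo.build_tube(100, 40, 0.5, 50, 2.5, False)
    params = fl.FlowParams(bc_kind="constant_shear_inlet",
                           inlet_wall_shear=500.0, **FAST)
    return dom, params, fl.solve_flow(dom, None, params)


class TestPoiseuilleTube:
    def test_flow_rate_matches_analytic(self, tube_solution):
        dom, params, f = tube_solution
        R = 20.0e-6  # m
        q_analytic = np.pi * 500.0 * R**3 / 4.0 * 1e9 * 60.0e3  # uL/min
        q_analytic = np.pi * 500.0 * (20.0) ** 3 / 4.0 * 60.0 / 1e9  # um^3/s -> uL/min
        assert f.converged
        assert f.Q == pytest.approx(q_analytic, rel=0.02)

    def test_mass_conservation_between_stations(self, tube_solution):
        dom, params, f = tube_solution
        qs = [fl.flow_rate(f, dom, s) for s in (2, 10, 20, 30, 37)]
        assert max(qs) / min(qs) - 1 < 0.01

    def test_linear_shear_profile(self, tube_solution):
        dom, params, f = tube_solution
        gamma = fl.shear_magnitude(f, dom).gamma
        c = dom.shape[1] // 2
        # centerline: symmetric flow, gamma ~ 0 relative to the wall value
        assert gamma[20, c, c] < 0.1 * 500.0
        # mid-radius voxel (r = 4 voxels off-axis): gamma = gamma_w r / R
        r_um = 4.5 * 2.5  # voxel center offset from axis
        expect = 500.0 * r_um / 20.0
        assert gamma[20, c + 4, c] == pytest.approx(expect, rel=0.05)

    def test_velocity_zero_on_solids(self, tube_solution):
        dom, params, f = tube_solution
        assert np.all(f.velocity[~dom.fluid_mask] == 0.0)

    def test_interior_divergence_small(self, tube_solution):
        dom, params, f = tube_solution
        u = f.velocity
        interior = dom.fluid_mask.copy()
        for ax in range(3):
            interior &= np.roll(dom.fluid_mask, 1, ax) & np.roll(dom.fluid_mask, -1, ax)
        interior[[0, -1]] = False
        div = np.zeros(dom.shape)
        h = dom.h
        for ax in range(3):
            div += (np.roll(u[..., ax], -1, ax) - np.roll(u[..., ax], 1, ax)) / (2 * h)
        umax = np.abs(u).max()
        assert np.abs(div[interior]).max() * h / umax < 0.02


class TestOcclusionAndBlockage:
    def test_occlusion_criterion_strict(self):
        assert fl.is_occluded(0.04, 1.0)
        assert not fl.is_occluded(1.0, 1.0)
        assert not fl.is_occluded(0.05, 1.0)  # exactly 5%: strictly "less than"
        with pytest.raises(ValueError):
            fl.is_occluded(0.1, 0.0)

    def test_fully_blocked_domain_returns_zero_flow(self, small_channel):
        occ = np.zeros(small_channel.shape, dtype=bool)
        occ[10] = True  # a full cross-sectional plug
        params = fl.FlowParams(inlet_wall_shear=200.0, **FAST)
        f = fl.solve_flow(small_channel, occ, params)
        assert f.converged
        assert f.Q == 0.0
        assert np.abs(f.velocity).max() == 0.0

    def test_pressure_drop_flow_decreases_with_occupancy(self):
        """Under fixed pressure drop, Q falls monotonically as a nested
        occupancy sequence grows."""
        dom = geo.build_tube(100, 40, 0.5, 50, 2.5, False)
        params = fl.FlowParams(bc_kind="constant_pressure_drop",
                               pressure_drop=20.0, **FAST)
        occ = np.zeros(dom.shape, dtype=bool)
        qs = []
        f = None
        for frac in (0.0, 0.3, 0.6):
            c = dom.shape[1] // 2
            half = int(np.ceil(frac * dom.shape[1] / 2))
            if half:
                occ[18:22, :, :] |= dom.fluid_mask[18:22]
                occ[18:22, :, half:] = False
            f = fl.solve_flow(dom, occ, params, warm_start=f)
            qs.append(f.Q)
        assert qs[0] > qs[1] > qs[2] > 0


class TestShearEstimators:
    def test_duct_floor_midline_shear(self):
        """Microfluidic-channel cross-section (250 x 60 um at h = 2.5): the
        imposed 200 1/s floor-midline wall shear is recovered within 5%."""
        dom = geo.build_channel(75, 250, 60, 0, 0, 2.5, False)
        params = fl.FlowParams(inlet_wall_shear=200.0, **FAST)
        f = fl.solve_flow(dom, None, params)
        ws = fl.wall_shear(f, dom)
        mid = dom.shape[1] // 2
        assert ws[15, mid, 0] == pytest.approx(200.0, rel=0.05)
        # strain-magnitude at the floor voxel center sits slightly below the
        # wall value (parabolic profile sampled half a voxel off the wall)
        gamma = fl.shear_magnitude(f, dom).gamma
        assert gamma[15, mid, 0] == pytest.approx(200.0 * (1 - 2.5 / 60.0), rel=0.05)

    def test_centerline_shear_vanishes(self, tube_solution):
        # with an even voxel count across the lumen the most-central voxel
        # sits h/sqrt(2) off-axis, where gamma/gamma_w = r/R ~ 0.09
        dom, params, f = tube_solution
        c = dom.shape[1] // 2
        gamma = fl.shear_magnitude(f, dom).gamma
        assert gamma[20, c, c] < 0.12 * gamma[20].max()


class TestResolutionConvergence:
    def test_tube_profile_error_decreases_with_refinement(self):
        errs = []
        for h in (5.0, 2.5):
            dom = geo.build_tube(50, 40, 0.5, 25, h, False)
            params = fl.FlowParams(inlet_wall_shear=500.0, **FAST)
            f = fl.solve_flow(dom, None, params)
            c = dom.shape[1] // 2
            station = dom.shape[0] // 2
            y = (np.arange(dom.shape[1]) + 0.5) * h - 20.0
            ana = fl.poiseuille_tube_profile(np.abs(y), 20.0, 500.0)
            sim = f.velocity[station, :, c, 0]
            sel = dom.fluid_mask[station, :, c]
            errs.append(np.abs(sim - ana)[sel].max() / ana.max())
        assert errs[1] < errs[0]


def test_flow_rate_station_bounds(tube_solution):
    dom, params, f = tube_solution
    with pytest.raises(IndexError):
        fl.flow_rate(f, dom, dom.shape[0])
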