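"""Simulator tests: sources, stepping, conservation, verification, 2-D."""
import math

import numpy as np
import pytest

from injeradry import properties as P
from injeradry.simulator import (
    DryingConditions,
    SampleGeometry,
    SolverSettings,
    advance,
    darcy_velocity,
    evaporation_sources,
    independence_study,
    initial_state,
    pore_vapour_split,
    simulate,
)
from injeradry.transfer import AirState

COMP = P.INJERA_COMPOSITION


def conditions(T_air=333.15, u=0.5, rh=11.0, **kw):
    return DryingConditions(air=AirState(T_air=T_air, u_air=u, RH=rh), **kw)


class TestEvaporationSources:
    def test_equilibrium_gives_zero(self):
        sm, sh = evaporation_sources(0.9, 5.0, 0.9 * 5.0, 1000.0)
        assert sm == 0.0 and sh == 0.0

    def test_evaporation_cools(self):
        sm, sh = evaporation_sources(0.99, 5.0, 0.5, 1000.0)
        assert sm > 0 and sh < 0
        assert sh == pytest.approx(-P.CONSTANTS.H_EVAP
                                   * P.CONSTANTS.M_VAPOUR * sm)

    def test_dry_pore_magnitude(self):
        _, cvs = P.saturation_state(333.15)
        sm, _ = evaporation_sources(0.99, cvs, 0.0, 1000.0)
        assert sm == pytest.approx(990.0 * cvs, rel=1e-12)

    def test_split_limits(self):
        # strong relaxation: pore vapour approaches local equilibrium
        cv = pore_vapour_split(0.9, 5.0, 0.5, 1e6, 0.2)
        assert cv == pytest.approx(4.5, rel=1e-5)
        # no relaxation: ventilation pins the pore gas at the air value
        cv = pore_vapour_split(0.9, 5.0, 0.5, 0.0, 0.2)
        assert cv == pytest.approx(0.5)


class TestDarcy:
    def test_off_by_default(self):
        u = darcy_velocity(np.array([0.0, 1000.0]), conditions(),
                           SolverSettings())
        assert np.all(u == 0.0)

    def test_zero_gradient(self):
        cond = conditions(intrinsic_permeability=1e-14)
        stg = SolverSettings(darcy="on")
        assert darcy_velocity(0.0, cond, stg) == 0.0

    def test_hand_value(self):
        cond = conditions(intrinsic_permeability=1e-14)
        stg = SolverSettings(darcy="on")
        u = darcy_velocity(1000.0, cond, stg, k_wr=0.5)
        # k_ii k_wr / mu * grad p with mu = 1.002e-3 Pa s
        assert float(u) == pytest.approx(1e-14 * 0.5 / 1.002e-3 * 1000.0,
                                         rel=1e-12)

    def test_missing_permeability(self):
        with pytest.raises(ValueError, match="intrinsic_permeability"):
            darcy_velocity(1.0, conditions(), SolverSettings(darcy="on"))


class TestAdvance:
    def test_equilibrium_fixed_point(self):
        """Air in equilibrium with the sample leaves the state unchanged."""
        rho = P.mixture_density(COMP, 298.15)
        x0 = P.concentration_to_dry_basis(49750.0, 0.74, rho)
        rh = 100.0 * P.water_activity(x0)
        cond = conditions(T_air=298.15, rh=rh)
        stg = SolverSettings()
        st = initial_state(COMP, SampleGeometry(), cond, stg)
        c0, T0 = st.c.copy(), st.T.copy()
        for _ in range(3):
            st = advance(st, cond, stg)
        assert np.max(np.abs(st.c - c0)) / 49750.0 < 1e-10
        assert np.max(np.abs(st.T - T0)) < 1e-8

    def test_conservation_closed_system(self):
        """No films, no sources: total moisture is exactly conserved."""
        cond = conditions(area_factor=0.0)
        stg = SolverSettings(sources=False)
        geom = SampleGeometry(n_z=31)
        st = initial_state(COMP, geom, cond, stg)
        # non-uniform start so diffusion actually moves moisture
        st.c = st.c * (1.0 + 0.3 * np.sin(np.linspace(0, np.pi, 31)))
        total0 = st.c.sum()
        spread0 = np.std(st.c)
        for _ in range(20):
            st = advance(st, cond, stg)
        assert st.c.sum() == pytest.approx(total0, rel=1e-8)
        assert np.std(st.c) < spread0  # diffusion smooths the profile

    def test_no_exchange_keeps_mr_at_one(self):
        cond = conditions(area_factor=0.0, K_vap=0.0, t_max=1800.0)
        curve = simulate(COMP, SampleGeometry(n_z=15), cond)
        assert curve.meta["truncated"]
        assert np.all(np.abs(curve.mr - 1.0) < 1e-10)


def analytic_slab(z, t, D, H, cs, c0, n_terms=80):
    """Series solution: slab 0..H, insulated base, surface held at cs."""
    th = np.zeros_like(z)
    for n in range(n_terms):
        lam = (2 * n + 1) * np.pi / (2 * H)
        th += ((-1)**n * 4 / ((2 * n + 1) * np.pi) * np.cos(lam * z)
               * np.exp(-D * lam**2 * t))
    return cs + (c0 - cs) * th


def run_slab(n_z, dt, t_end, D=1e-7, cs=5000.0):
    geom = SampleGeometry(n_z=n_z)
    cond = conditions(T_air=298.15, rh=50.0)
    stg = SolverSettings(dt=dt, sources=False, surface_bc="dirichlet",
                         surface_value=cs, constant_diffusivity=D)
    st = initial_state(COMP, geom, cond, stg)
    for _ in range(int(round(t_end / dt))):
        st = advance(st, cond, stg)
    z = (np.arange(n_z) + 0.5) * 0.03 / n_z
    return np.max(np.abs(st.c - analytic_slab(z, t_end, D, 0.03, cs,
                                              49750.0))) / (49750.0 - cs)


class TestVerification:
    def test_matches_analytic_slab_solution(self):
        """Constant-D diffusion agrees with the Fourier series within 1 %."""
        assert run_slab(n_z=41, dt=2.0, t_end=900.0) < 0.01

    def test_spatial_convergence_order(self):
        """Observed spatial order >= 1.8 (dt refined with dz to isolate it)."""
        errs = {}
        for n_z in (11, 21, 41):
            dt = 4.0 * (11 / n_z) ** 2
            dt = 900.0 / round(900.0 / dt)
            errs[n_z] = run_slab(n_z=n_z, dt=dt, t_end=900.0)
        orders = [math.log(errs[a] / errs[b]) / math.log(2)
                  for a, b in ((11, 21), (21, 41))]
        assert min(orders) >= 1.8


class TestSimulate:
    def test_reference_curve_shape(self, curve_333):
        assert curve_333.mr[0] == pytest.approx(1.0, abs=1e-12)
        assert np.all(np.diff(curve_333.mr) <= 1e-12)   # non-increasing
        assert not curve_333.meta["truncated"]

    def test_temperature_bounds(self, curve_333, curve_323):
        for curve, ta in ((curve_333, 333.15), (curve_323, 323.15)):
            assert curve.T_center.min() >= 298.15 - 0.5
            assert curve.T_center.max() <= ta + 0.5
            assert curve.T_mean.min() >= 298.15 - 0.5

    def test_balance_closure(self, curve_333):
        bal = curve_333.meta["balance"]
        assert abs(bal["relative_closure_error"]) < 0.01
        assert bal["volumetric_source_mol_m2"] > 0
        assert bal["boundary_mol_m2"] > 0

    def test_truncation_flag(self):
        cond = conditions(t_max=60.0)
        curve = simulate(COMP, SampleGeometry(n_z=15), cond)
        assert curve.meta["truncated"]

    def test_time_step_halving_changes_mr_little(self):
        """dt 60 -> 30 s moves MR(t) by < 0.005 on the unit MR scale."""
        cond = conditions()
        geom = SampleGeometry(n_z=31)
        c60 = simulate(COMP, geom, cond, SolverSettings(dt=60))
        c30 = simulate(COMP, geom, cond, SolverSettings(dt=30))
        t = np.arange(0.0, min(c60.t_min[-1], c30.t_min[-1]), 1.0)
        d = np.abs(np.interp(t, c60.t_min, c60.mr)
                   - np.interp(t, c30.t_min, c30.mr))
        assert d.max() < 5e-3

    def test_picard_reported(self, curve_333):
        assert 1 <= curve_333.meta["picard"]["max"] <= 50


class TestIndependence:
    def test_refinement_increments_decrease(self):
        cond = conditions()
        rep = independence_study(COMP, SampleGeometry(), cond,
                                 grid_levels=(9, 17, 33, 65),
                                 dt_levels=(300.0, 150.0, 75.0))
        grid_changes = [lvl["rel_change"] for lvl in rep["grid"][1:]]
        assert np.all(np.diff(grid_changes) < 0)
        dt_changes = [lvl["rel_change"] for lvl in rep["dt"][1:]]
        assert np.all(np.diff(dt_changes) < 0)

    def test_coarsest_grid_not_converged(self):
        cond = conditions()
        rep = independence_study(COMP, SampleGeometry(), cond,
                                 grid_levels=(3, 7, 15),
                                 dt_levels=(600.0, 300.0, 150.0))
        assert not rep["grid"][1]["converged"]

    def test_requires_three_levels(self):
        with pytest.raises(ValueError):
            independence_study(COMP, SampleGeometry(), conditions(),
                               grid_levels=(11, 21), dt_levels=(60.0, 30.0))


class TestAxisymmetric:
    def test_2d_runs_and_respects_bounds(self):
        geom = SampleGeometry(mode="axisym2d", n_z=15, n_r=7)
        curve = simulate(COMP, geom, conditions())
        assert not curve.meta["truncated"]
        assert np.all(np.diff(curve.mr) <= 1e-12)
        assert curve.T_center.max() <= 333.15 + 0.5
        assert curve.T_center.min() >= 298.15 - 0.5
        assert abs(curve.meta["balance"]["relative_closure_error"]) < 0.01

    def test_rim_exchange_speeds_drying(self):
        geom2 = SampleGeometry(mode="axisym2d", n_z=15, n_r=7)
        geom1 = SampleGeometry(n_z=15)
        t2 = simulate(COMP, geom2, conditions()).drying_time(0.03)
        t1 = simulate(COMP, geom1, conditions()).drying_time(0.03)
        assert t2 < t1
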