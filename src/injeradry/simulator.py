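"""Finite-volume solver for the coupled moisture and energy equations.

Model
-----
A single field c (mol/m^3) tracks the total moisture of the porous sample;
T is the local temperature.  On the sample grid (1-D through-thickness by
default, optionally 2-D axisymmetric) the solver integrates

    dc/dt = div(D grad c) - u_d . grad c - Sm
    (rho cp)_eff dT/dt = div(k_eff grad T) - (rho_f cp_f) u_d . grad T + Sh

with backward-Euler time stepping and Picard iteration over the nonlinear
coefficients and sources (sources linearized in the solved variable for
robustness).

Evaporation is the non-equilibrium volumetric source

    Sm = K_vap (aw(X) cv_sat(T) - c_v),    Sh = -H_evap M_v Sm

where the pore vapour concentration c_v follows a quasi-steady balance
between the K_vap relaxation towards local equilibrium and exchange with
the drying air at the pore-ventilation rate N (see ``pore_vapour_split``),
which collapses the source to  Sm = G (aw cv_sat - Ca)  with
G = K_vap N / (K_vap + N).  For K_vap well above N the source is
insensitive to K_vap, which is the intended "strong evaporation" regime.

Moisture transport combines a constant capillary diffusivity with the
gas-phase effective diffusivity applied to the vapour share of the local
moisture (chain rule d c_v / d c), so gas diffusion matters only where the
isotherm is steep.  Boundary faces exchange heat and vapour with the air
through the correlation film coefficients, enhanced by a common
exchange-area factor for the open pore surface.

Evaporated vapour is swept to the air stream by the ventilation exchange;
it leaves the balance through the source bookkeeping, which the run report
closes against storage change and boundary flux.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import solve_banded
from scipy.sparse import coo_matrix
from scipy.sparse.linalg import spsolve

from . import properties as props
from .curve import DryingCurve
from .transfer import AirState, far_field_vapour_concentration, transfer_coefficients

__all__ = [
    "SampleGeometry",
    "DryingConditions",
    "SolverSettings",
    "FieldState",
    "StepError",
    "pore_vapour_split",
    "evaporation_sources",
    "darcy_velocity",
    "initial_state",
    "advance",
    "simulate",
    "independence_study",
]

log = logging.getLogger(__name__)

LAM_MOL = props.CONSTANTS.H_EVAP * props.CONSTANTS.M_VAPOUR  # J/mol evaporated


class StepError(RuntimeError):
    """A time step failed (non-convergence or unphysical state)."""


@dataclass(frozen=True)
class SampleGeometry:
    """Sample slab: 3 cm thick, 30 cm diameter by default."""

    thickness: float = 0.03     # m
    diameter: float = 0.30      # m
    mode: str = "1d"            # "1d" | "axisym2d"
    n_z: int = 61
    n_r: int = 31

    def __post_init__(self) -> None:
        if self.thickness <= 0 or self.diameter <= 0:
            raise ValueError("geometry dimensions must be positive")
        if self.mode not in ("1d", "axisym2d"):
            raise ValueError(f"unknown geometry mode '{self.mode}'")
        if self.n_z < 3 or (self.mode == "axisym2d" and self.n_r < 3):
            raise ValueError("need at least 3 nodes per resolved direction")


@dataclass(frozen=True)
class DryingConditions:
    """Air state, evaporation closure and stopping rule for one run.

    K_vap is the non-equilibrium evaporation rate constant; the result is
    insensitive to it above ~100 1/s because the pore-ventilation rate
    ``vent_rate`` (N) limits the collapsed source.  ``area_factor``
    multiplies both film coefficients (open-pore exchange surface);
    ``capillary_diffusivity`` is the liquid-moisture diffusivity of the
    wet matrix.  The three closure constants were fixed once against the
    reference tunnel conditions and are ordinary config entries.
    """

    air: AirState = field(default_factory=AirState)
    K_vap: float = 1000.0               # 1/s
    vent_rate: float = 0.2              # 1/s
    area_factor: float = 20.5           # dimensionless
    capillary_diffusivity: float = 1.61e-7  # m^2/s
    MR_stop: float = 0.03
    t_max: float = 86400.0              # s
    c0: float = 49750.0                 # initial moisture, mol/m^3
    T0: float = 298.15                  # initial temperature, K
    eps: float = 0.74                   # porosity
    pressure_gradient: float = 0.0      # Pa/m, used only with darcy on
    intrinsic_permeability: float | None = None  # m^2

    def __post_init__(self) -> None:
        if self.K_vap < 0 or self.vent_rate < 0:
            raise ValueError("rate constants must be non-negative")
        if not 0.0 < self.MR_stop < 1.0:
            raise ValueError("MR_stop must be in (0, 1)")
        if self.t_max <= 0 or self.c0 <= 0:
            raise ValueError("t_max and c0 must be positive")


@dataclass(frozen=True)
class SolverSettings:
    dt: float = 60.0                 # s
    picard_tol: float = 1e-8         # relative moisture change per sweep
    picard_max: int = 50
    mixture_rule: str = "as_printed"  # "as_printed" | "corrected"
    darcy: str = "off"               # "off" | "on"
    bottom: str = "insulated"        # "insulated" | "convective"
    surface_bc: str = "film"         # "film" | "dirichlet"
    surface_value: float | None = None   # mol/m^3, dirichlet only
    constant_diffusivity: float | None = None  # m^2/s override (verification)
    sources: bool = True             # volumetric evaporation on/off

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.picard_tol <= 0:
            raise ValueError("dt and picard_tol must be positive")
        if self.mixture_rule not in ("as_printed", "corrected"):
            raise ValueError("mixture_rule must be as_printed or corrected")


@dataclass
class FieldState:
    """Nodal moisture and temperature at one instant.

    Arrays are flattened C-order over (r, z) in 2-D mode; z runs from the
    tray (bottom) to the exposed surface (top).
    """

    t: float
    c: np.ndarray
    T: np.ndarray
    geometry: SampleGeometry
    comp: props.Composition
    eps: float
    T0: float

    def sources(self, conditions: DryingConditions
                ) -> tuple[np.ndarray, np.ndarray]:
        """Per-node evaporation sources (Sm, Sh) at this state."""
        ctx = _RunContext(self.comp, self.geometry, conditions,
                          SolverSettings())
        x = ctx.x_db(self.c)
        aw = props.water_activity(np.maximum(x, 1e-12))
        _, cvs = props.saturation_state(self.T)
        c_v = pore_vapour_split(aw, cvs, ctx.Ca, conditions.K_vap,
                                conditions.vent_rate)
        return evaporation_sources(aw, cvs, c_v, conditions.K_vap)


# ---------------------------------------------------------------------------
# sources
# ---------------------------------------------------------------------------

def pore_vapour_split(aw, cv_sat, c_a: float, k_vap: float, vent_rate: float):
    """Quasi-steady pore vapour concentration, mol/m^3.

    Production K_vap (aw cv_sat - c_v) balances ventilation N (c_v - Ca):
    c_v = (K_vap aw cv_sat + N Ca) / (K_vap + N).
    """
    denom = k_vap + vent_rate
    if denom <= 0:
        return np.asarray(aw) * np.asarray(cv_sat)  # no exchange: equilibrium
    return (k_vap * np.asarray(aw) * np.asarray(cv_sat)
            + vent_rate * c_a) / denom


def evaporation_sources(aw, cv_sat, c_v, k_vap: float
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Sm = K_vap (aw cv_sat - c_v) and Sh = -H_evap M_v Sm.

    Sm > 0 is evaporation (moisture sink); the matching Sh < 0 is the
    evaporative cooling of the matrix.  Negative drives (condensation) are
    clamped to zero.
    """
    sm = k_vap * np.maximum(np.asarray(aw) * np.asarray(cv_sat)
                            - np.asarray(c_v), 0.0)
    return sm, -LAM_MOL * sm


def darcy_velocity(pressure_gradient, conditions: DryingConditions,
                   settings: SolverSettings, k_wr: float = 1.0):
    """Pore-liquid Darcy velocity u = (k_ii k_wr / mu) grad p, m/s.

    Zero when the darcy flag is off (the default: no internal pressure
    equation is posed).
    """
    if settings.darcy == "off":
        return np.zeros_like(np.asarray(pressure_gradient, dtype=float))
    if conditions.intrinsic_permeability is None:
        raise ValueError("darcy flag is on but intrinsic_permeability "
                         "is not configured")
    k_i = conditions.intrinsic_permeability * k_wr
    return (k_i / props.CONSTANTS.MU_WATER
            * np.asarray(pressure_gradient, dtype=float))


# ---------------------------------------------------------------------------
# run context (per-run constants and grids)
# ---------------------------------------------------------------------------

class _RunContext:
    def __init__(self, comp: props.Composition, geom: SampleGeometry,
                 cond: DryingConditions, settings: SolverSettings):
        self.comp, self.geom, self.cond, self.settings = (
            comp, geom, cond, settings)
        C = props.CONSTANTS
        T_air = cond.air.T_air
        # solid-matrix properties frozen at the air temperature for the run
        self.rho_p = props.mixture_density(comp, T_air)
        self.cp_p = props.mixture_specific_heat(comp, T_air)
        self.k_p = props.mixture_conductivity(comp, T_air)
        self.eps = cond.eps
        self.dry_mass = (1.0 - self.eps) * self.rho_p
        self.Ca = far_field_vapour_concentration(cond.air)
        self.Me = props.equilibrium_moisture(max(cond.air.RH / 100.0, 1e-4))
        self.X0 = cond.c0 * C.M_WATER / self.dry_mass
        g = cond.K_vap + cond.vent_rate
        self.G = (cond.K_vap * cond.vent_rate / g if g > 0 else 0.0)
        if not settings.sources:
            self.G = 0.0
        # film coefficients from the initial (wet) surface state
        bundle0 = props.evaluate_bundle(comp, T_air, cond.c0, self.eps,
                                        cond.T0, settings.mixture_rule)
        self.tc = transfer_coefficients(cond.air, geom.diameter,
                                        bundle0.k_eff, cond.area_factor)
        # grid
        self.n_z = geom.n_z
        self.dz = geom.thickness / geom.n_z
        if geom.mode == "axisym2d":
            self.n_r = geom.n_r
            self.dr = geom.diameter / 2.0 / geom.n_r
            r = (np.arange(self.n_r) + 0.5) * self.dr
            vol = (r * self.dr * self.dz)          # per radian
            self.volumes = np.repeat(vol, self.n_z)
            self.n_cells = self.n_r * self.n_z
        else:
            self.n_r = 1
            self.volumes = np.full(geom.n_z, self.dz)
            self.n_cells = geom.n_z

    # state-dependent coefficient arrays -----------------------------------
    def x_db(self, c: np.ndarray) -> np.ndarray:
        return c * props.CONSTANTS.M_WATER / self.dry_mass

    def moisture_diffusivity(self, c, T, aw, cvs) -> np.ndarray:
        if self.settings.constant_diffusivity is not None:
            return np.full_like(np.asarray(c, dtype=float),
                                self.settings.constant_diffusivity)
        C = props.CONSTANTS
        s_w = np.clip(c * C.M_WATER / (self.eps * C.RHO_WATER), 0.0, 1.0)
        s_g = 1.0 - s_w
        d_gas = props.effective_gas_diffusivity(self.eps, s_g)
        dcv_dc = np.clip(cvs * self._daw_dx(self.x_db(c))
                         * C.M_WATER / self.dry_mass, 0.0, 1.0)
        return self.cond.capillary_diffusivity + d_gas * dcv_dc

    @staticmethod
    def _daw_dx(x: np.ndarray) -> np.ndarray:
        x = np.maximum(x, 1e-9)
        h = 1e-7 + 1e-7 * x
        return (props.water_activity(x + h)
                - props.water_activity(np.maximum(x - h, 1e-10))) / (2 * h)

    @staticmethod
    def _dcvs_dT(T: np.ndarray) -> np.ndarray:
        h = 1e-3
        return (props.saturation_state(T + h)[1]
                - props.saturation_state(T - h)[1]) / (2 * h)

    def thermal_arrays(self, c, T):
        """(rho cp)_eff and k_eff per node for the configured mixture rule."""
        C = props.CONSTANTS
        s_w = np.clip(c * C.M_WATER / (self.eps * C.RHO_WATER), 0.0, 1.0)
        s_g = 1.0 - s_w
        _, cvs = props.saturation_state(T)
        m_vap = cvs * C.M_VAPOUR * s_g
        m_liq = C.RHO_WATER * s_w
        with np.errstate(invalid="ignore"):
            x_v = np.where(m_vap + m_liq > 0, m_vap / (m_vap + m_liq), 1.0)
        k_f = C.K_WATER - (C.K_WATER - C.K_AIR) * x_v
        rho_f = C.RHO_WATER - (C.RHO_WATER - C.RHO_AIR) * x_v
        cp_f = C.CP_WATER - (C.CP_WATER - C.CP_AIR) * x_v
        if self.settings.mixture_rule == "as_printed":
            rho_cp = self.rho_p * self.cp_p - (1.0 - self.eps) * rho_f * cp_f
            k_eff = self.eps * self.k_p + (1.0 - self.eps) * k_f
        else:
            rho_cp = ((1.0 - self.eps) * self.rho_p * self.cp_p
                      + self.eps * rho_f * cp_f)
            k_eff = (1.0 - self.eps) * self.k_p + self.eps * k_f
        return rho_cp, k_eff

    def mean_mr(self, c: np.ndarray) -> float:
        x_mean = float(np.average(self.x_db(c), weights=self.volumes))
        return (x_mean - self.Me) / (self.X0 - self.Me)


# ---------------------------------------------------------------------------
# linear solvers
# ---------------------------------------------------------------------------

def _solve_tridiag(lo, di, up, b):
    n = len(b)
    ab = np.zeros((3, n))
    ab[0, 1:] = up[:-1]
    ab[1] = di
    ab[2, :-1] = lo[1:]
    return solve_banded((1, 1), ab, b)


# ---------------------------------------------------------------------------
# time stepping
# ---------------------------------------------------------------------------

def initial_state(comp: props.Composition, geometry: SampleGeometry,
                  conditions: DryingConditions,
                  settings: SolverSettings | None = None) -> FieldState:
    settings = settings or SolverSettings()
    ctx = _RunContext(comp, geometry, conditions, settings)
    n = ctx.n_cells
    return FieldState(t=0.0, c=np.full(n, conditions.c0),
                      T=np.full(n, conditions.T0), geometry=geometry,
                      comp=comp, eps=conditions.eps, T0=conditions.T0)


def _step_1d(ctx: _RunContext, c_old: np.ndarray, T_old: np.ndarray,
             dt: float) -> tuple[np.ndarray, np.ndarray, dict]:
    """One backward-Euler step on the 1-D grid.  Returns (c, T, info)."""
    cond, settings = ctx.cond, ctx.settings
    C = props.CONSTANTS
    n = ctx.n_z
    dz = ctx.dz
    hT, hm = ctx.tc.hT, ctx.tc.hm
    Ta, Ca = cond.air.T_air, ctx.Ca
    c, T = c_old.copy(), T_old.copy()
    dirichlet = settings.surface_bc == "dirichlet"
    cs_fixed = settings.surface_value if dirichlet else None
    # optional Darcy advection (upwind, constant velocity)
    if settings.darcy == "on":
        u_d = float(darcy_velocity(cond.pressure_gradient, cond, settings))
    else:
        u_d = 0.0

    info = {"picard": 0}
    for sweep in range(settings.picard_max):
        x = ctx.x_db(c)
        aw = props.water_activity(np.maximum(x, 1e-12))
        _, cvs = props.saturation_state(T)
        D = ctx.moisture_diffusivity(c, T, aw, cvs)
        drive = aw * cvs - Ca
        act = drive > 0
        sm0 = ctx.G * np.where(act, drive, 0.0)
        dsm_dc = ctx.G * np.where(
            act, cvs * ctx._daw_dx(x) * C.M_WATER / ctx.dry_mass, 0.0)

        # ---- moisture ----
        df = np.where(D[:-1] + D[1:] > 0,
                      2 * D[:-1] * D[1:] / (D[:-1] + D[1:] + 1e-300), 0.0)
        a = df / dz**2
        lo = np.zeros(n); di = np.full(n, 1.0 / dt); up = np.zeros(n)
        di[:-1] += a; di[1:] += a
        up[:-1] = -a; lo[1:] = -a
        di += dsm_dc
        b = c_old / dt - sm0 + dsm_dc * c
        if u_d != 0.0:  # implicit first-order upwind advection
            w = abs(u_d) / dz
            if u_d > 0:
                di[1:] += w
                lo[1:] += -w
            else:
                di[:-1] += w
                up[:-1] += -w
        if dirichlet:
            # surface face held at cs_fixed: half-cell conductance
            g_s = D[-1] / (dz / 2) / dz
            di[-1] += g_s
            b[-1] += g_s * cs_fixed
        else:
            fs = hm * max(drive[-1], 0.0)
            dfs = (hm * cvs[-1] * ctx._daw_dx(x[-1:])[0]
                   * C.M_WATER / ctx.dry_mass if drive[-1] > 0 else 0.0)
            di[-1] += dfs / dz
            b[-1] += (-fs + dfs * c[-1]) / dz
        if settings.bottom == "convective" and not dirichlet:
            fb = hm * max(drive[0], 0.0)
            dfb = (hm * cvs[0] * ctx._daw_dx(x[:1])[0]
                   * C.M_WATER / ctx.dry_mass if drive[0] > 0 else 0.0)
            di[0] += dfb / dz
            b[0] += (-fb + dfb * c[0]) / dz
        c_new = _solve_tridiag(lo, di, up, b)

        # ---- energy ----
        x2 = ctx.x_db(np.maximum(c_new, 0.0))
        aw2 = props.water_activity(np.maximum(x2, 1e-12))
        drive2 = aw2 * cvs - Ca
        act2 = drive2 > 0
        sm1 = ctx.G * np.where(act2, drive2, 0.0)
        dcvs = ctx._dcvs_dT(T)
        dsm_dT = ctx.G * np.where(act2, aw2 * dcvs, 0.0)
        rho_cp, k_eff = ctx.thermal_arrays(np.maximum(c_new, 0.0), T)
        ak = np.where(k_eff[:-1] + k_eff[1:] > 0,
                      2 * k_eff[:-1] * k_eff[1:]
                      / (k_eff[:-1] + k_eff[1:] + 1e-300), 0.0) / dz**2
        alo = np.zeros(n); adi = rho_cp / dt; aup = np.zeros(n)
        adi = np.array(adi, dtype=float)
        adi[:-1] += ak; adi[1:] += ak
        aup[:-1] = -ak; alo[1:] = -ak
        adi += LAM_MOL * dsm_dT
        bT = rho_cp * T_old / dt - LAM_MOL * sm1 + LAM_MOL * dsm_dT * T
        # surface: convective heating and evaporative cooling of film flux
        if not dirichlet:
            fs2 = hm * max(drive2[-1], 0.0)
            dfs2 = hm * aw2[-1] * dcvs[-1] if drive2[-1] > 0 else 0.0
            adi[-1] += (hT + LAM_MOL * dfs2) / dz
            bT[-1] += (hT * Ta - LAM_MOL * fs2 + LAM_MOL * dfs2 * T[-1]) / dz
        else:
            adi[-1] += hT / dz
            bT[-1] += hT * Ta / dz
        if settings.bottom == "convective":
            adi[0] += hT / dz
            bT[0] += hT * Ta / dz
        T_new = _solve_tridiag(alo, adi, aup, bT)

        dc_rel = float(np.max(np.abs(c_new - c)) / max(np.max(np.abs(c_new)),
                                                       1.0))
        dT_abs = float(np.max(np.abs(T_new - T)))
        c, T = c_new, T_new
        info["picard"] = sweep + 1
        if dc_rel < settings.picard_tol and dT_abs < 1e-6:
            break
    else:
        raise StepError(
            f"Picard iteration did not converge in {settings.picard_max} "
            f"sweeps (last dc_rel={dc_rel:.2e}, dT={dT_abs:.2e} K)")

    # clip guard: tiny negatives are floored, larger ones are an error
    floor = -1e-9 * ctx.cond.c0
    if np.any(c < floor):
        raise StepError(f"negative moisture concentration {c.min():.3e} "
                        "after step")
    clipped = float(np.sum(np.minimum(c, 0.0) * ctx.volumes))
    if np.any(c < 0):
        log.warning("clipped %.2e mol/m^2 negative moisture", -clipped)
        c = np.maximum(c, 0.0)

    # converged-state fluxes for the balance bookkeeping
    x = ctx.x_db(c)
    aw = props.water_activity(np.maximum(x, 1e-12))
    _, cvs = props.saturation_state(T)
    drive = aw * cvs - Ca
    sm = ctx.G * np.maximum(drive, 0.0)
    if dirichlet:
        flux_top = float(D[-1] * (c[-1] - cs_fixed) / (dz / 2))
    else:
        flux_top = float(hm * max(drive[-1], 0.0))
    if settings.bottom == "convective" and not dirichlet:
        flux_top += float(hm * max(drive[0], 0.0))
    info.update(
        boundary_flux=flux_top,                        # mol/(m^2 s)
        source_total=float(np.sum(sm * ctx.volumes)),  # mol/(m^2 s)
        clipped=-clipped,
    )
    return c, T, info


def _step_2d(ctx: _RunContext, c_old, T_old, dt):
    """Backward-Euler step on the axisymmetric (r, z) grid."""
    cond, settings = ctx.cond, ctx.settings
    C = props.CONSTANTS
    n_r, n_z = ctx.n_r, ctx.n_z
    dz, dr = ctx.dz, ctx.dr
    n = ctx.n_cells
    hT, hm = ctx.tc.hT, ctx.tc.hm
    Ta, Ca = cond.air.T_air, ctx.Ca
    vols = ctx.volumes
    r_cell = (np.arange(n_r) + 0.5) * dr
    top_area = r_cell * dr                    # per radian
    rim_area = (n_r * dr) * dz                # per radian, per rim cell
    idx = np.arange(n).reshape(n_r, n_z)
    top_cells = idx[:, -1]
    bot_cells = idx[:, 0]
    rim_cells = idx[-1, :]

    def diffusion_matrix(coeff):
        rows, cols, vals = [], [], []
        cf = coeff.reshape(n_r, n_z)
        # vertical faces
        d1, d2 = cf[:, :-1], cf[:, 1:]
        harm = np.where(d1 + d2 > 0, 2 * d1 * d2 / (d1 + d2 + 1e-300), 0.0)
        tr = harm * (r_cell * dr)[:, None] / dz
        k1 = idx[:, :-1].ravel(); k2 = idx[:, 1:].ravel(); t = tr.ravel()
        rows += [*k1, *k1, *k2, *k2]
        cols += [*k1, *k2, *k2, *k1]
        vals += [*t, *(-t), *t, *(-t)]
        # radial faces
        d1, d2 = cf[:-1, :], cf[1:, :]
        harm = np.where(d1 + d2 > 0, 2 * d1 * d2 / (d1 + d2 + 1e-300), 0.0)
        r_face = (np.arange(1, n_r) * dr)[:, None]
        tr = harm * r_face * dz / dr
        k1 = idx[:-1, :].ravel(); k2 = idx[1:, :].ravel(); t = tr.ravel()
        rows += [*k1, *k1, *k2, *k2]
        cols += [*k1, *k2, *k2, *k1]
        vals += [*t, *(-t), *t, *(-t)]
        return rows, cols, vals

    c, T = c_old.copy(), T_old.copy()
    info = {"picard": 0}
    for sweep in range(settings.picard_max):
        x = ctx.x_db(c)
        aw = props.water_activity(np.maximum(x, 1e-12))
        _, cvs = props.saturation_state(T)
        D = ctx.moisture_diffusivity(c, T, aw, cvs)
        drive = aw * cvs - Ca
        act = drive > 0
        sm0 = ctx.G * np.where(act, drive, 0.0)
        dsm_dc = ctx.G * np.where(
            act, cvs * ctx._daw_dx(x) * C.M_WATER / ctx.dry_mass, 0.0)

        rows, cols, vals = diffusion_matrix(D)
        diag = vols / dt + dsm_dc * vols
        b = (c_old / dt - sm0 + dsm_dc * c) * vols
        # film faces: top, rim (and bottom if convective)
        film = [(top_cells, top_area)]
        film.append((rim_cells, np.full(n_z, rim_area)))
        if settings.bottom == "convective":
            film.append((bot_cells, top_area))
        extra_rows, extra_vals = [], []
        for cells, areas in film:
            f = hm * np.maximum(drive[cells], 0.0)
            dfdc = np.where(drive[cells] > 0,
                            hm * cvs[cells] * ctx._daw_dx(x[cells])
                            * C.M_WATER / ctx.dry_mass, 0.0)
            b[cells] += (-f + dfdc * c[cells]) * areas
            extra_rows.append(cells)
            extra_vals.append(dfdc * areas)
        rows2 = list(rows) + [*np.arange(n)]
        cols2 = list(cols) + [*np.arange(n)]
        vals2 = list(vals) + [*diag]
        for cells, ev in zip([f[0] for f in film], extra_vals):
            rows2 += [*cells]; cols2 += [*cells]; vals2 += [*ev]
        A = coo_matrix((vals2, (rows2, cols2)), shape=(n, n)).tocsr()
        c_new = spsolve(A, b)

        # energy
        x2 = ctx.x_db(np.maximum(c_new, 0.0))
        aw2 = props.water_activity(np.maximum(x2, 1e-12))
        drive2 = aw2 * cvs - Ca
        sm1 = ctx.G * np.maximum(drive2, 0.0)
        dcvs = ctx._dcvs_dT(T)
        dsm_dT = ctx.G * np.where(drive2 > 0, aw2 * dcvs, 0.0)
        rho_cp, k_eff = ctx.thermal_arrays(np.maximum(c_new, 0.0), T)
        rows, cols, vals = diffusion_matrix(k_eff)
        diag = rho_cp * vols / dt + LAM_MOL * dsm_dT * vols
        bT = (rho_cp * T_old / dt - LAM_MOL * sm1
              + LAM_MOL * dsm_dT * T) * vols
        for cells, areas in film:
            fs2 = hm * np.maximum(drive2[cells], 0.0)
            dfs2 = np.where(drive2[cells] > 0, hm * aw2[cells] * dcvs[cells],
                            0.0)
            bT[cells] += (hT * Ta - LAM_MOL * fs2
                          + LAM_MOL * dfs2 * T[cells]) * areas
            rows += [*cells]; cols += [*cells]
            vals += [*((hT + LAM_MOL * dfs2) * areas)]
        rows += [*np.arange(n)]; cols += [*np.arange(n)]; vals += [*diag]
        A = coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
        T_new = spsolve(A, bT)

        dc_rel = float(np.max(np.abs(c_new - c)) / max(np.max(np.abs(c_new)),
                                                       1.0))
        dT_abs = float(np.max(np.abs(T_new - T)))
        c, T = c_new, T_new
        info["picard"] = sweep + 1
        if dc_rel < settings.picard_tol and dT_abs < 1e-6:
            break
    else:
        raise StepError(f"Picard iteration did not converge "
                        f"(dc_rel={dc_rel:.2e}, dT={dT_abs:.2e} K)")
    if np.any(c < -1e-9 * cond.c0):
        raise StepError(f"negative moisture {c.min():.3e} after step")
    c = np.maximum(c, 0.0)

    x = ctx.x_db(c)
    aw = props.water_activity(np.maximum(x, 1e-12))
    _, cvs = props.saturation_state(T)
    drive = aw * cvs - Ca
    sm = ctx.G * np.maximum(drive, 0.0)
    area_total = float(np.sum(top_area))
    bflux = float(np.sum(hm * np.maximum(drive[top_cells], 0.0) * top_area))
    bflux += float(np.sum(hm * np.maximum(drive[rim_cells], 0.0)) * rim_area)
    if settings.bottom == "convective":
        bflux += float(np.sum(hm * np.maximum(drive[bot_cells], 0.0)
                              * top_area))
    info.update(
        boundary_flux=bflux / area_total,
        source_total=float(np.sum(sm * vols)) / area_total,
        clipped=0.0,
    )
    return c, T, info


def advance(state: FieldState, conditions: DryingConditions,
            settings: SolverSettings) -> FieldState:
    """Advance the field state by one implicit time step."""
    ctx = _RunContext(state.comp, state.geometry, conditions, settings)
    step = _step_2d if state.geometry.mode == "axisym2d" else _step_1d
    c, T, _ = step(ctx, state.c, state.T, settings.dt)
    return replace(state, t=state.t + settings.dt, c=c, T=T)


# ---------------------------------------------------------------------------
# full simulation
# ---------------------------------------------------------------------------

def simulate(comp: props.Composition, geometry: SampleGeometry,
             conditions: DryingConditions,
             settings: SolverSettings | None = None) -> DryingCurve:
    """Run a drying simulation until MR <= MR_stop or t_max.

    Returns the drying curve (times in minutes, volume-averaged MR, centre
    and mean temperature, surface flux); the run report in ``meta``
    carries the moisture balance closure, Picard statistics and a
    truncation flag when t_max is hit first.
    """
    settings = settings or SolverSettings()
    ctx = _RunContext(comp, geometry, conditions, settings)
    step = _step_2d if geometry.mode == "axisym2d" else _step_1d
    state = initial_state(comp, geometry, conditions, settings)
    c, T = state.c, state.T
    vols = ctx.volumes
    area = float(np.sum(vols)) / geometry.thickness  # plan area (per radian)
    center = (ctx.n_z // 2 if geometry.mode == "1d"
              else 0 * ctx.n_z + ctx.n_z // 2)      # axis mid-thickness

    t = 0.0
    times = [0.0]
    mrs = [ctx.mean_mr(c)]
    t_center = [float(T[center])]
    t_mean = [float(np.average(T, weights=vols))]
    fluxes = [0.0]
    out_boundary = 0.0
    out_source = 0.0
    clipped = 0.0
    picard_counts = []
    truncated = False
    while True:
        if mrs[-1] <= conditions.MR_stop:
            break
        if t >= conditions.t_max:
            truncated = True
            log.warning("t_max reached at MR=%.4f before MR_stop=%.3f",
                        mrs[-1], conditions.MR_stop)
            break
        m_before = float(np.sum(c * vols))
        c, T, info = step(ctx, c, T, settings.dt)
        t += settings.dt
        m_after = float(np.sum(c * vols))
        # accumulate the converged end-of-step rates; the closure error
        # against the storage change measures the residual of the
        # linearized implicit sources
        out_boundary += info["boundary_flux"] * settings.dt
        out_source += info["source_total"] * settings.dt
        clipped += info.get("clipped", 0.0)
        picard_counts.append(info["picard"])
        times.append(t / 60.0)
        mrs.append(ctx.mean_mr(c))
        t_center.append(float(T[center]))
        t_mean.append(float(np.average(T, weights=vols)))
        fluxes.append(info["boundary_flux"])
        log.debug("t=%6.1f min MR=%.4f T_c=%.2f K picard=%d",
                  t / 60, mrs[-1], t_center[-1], info["picard"])

    m0 = conditions.c0 * float(np.sum(vols)) / area
    m_end = float(np.sum(c * vols)) / area
    lost = m0 - m_end
    closure = (lost - (out_boundary + out_source)) / lost if lost > 0 else 0.0
    meta = {
        "source": "simulated",
        "T_air_K": conditions.air.T_air,
        "u_air_m_s": conditions.air.u_air,
        "RH_pct": conditions.air.RH,
        "Me": ctx.Me,
        "Mo": ctx.X0,
        "MR_stop": conditions.MR_stop,
        "truncated": truncated,
        "balance": {
            "moisture_lost_mol_m2": lost,
            "boundary_mol_m2": out_boundary,
            "volumetric_source_mol_m2": out_source,
            "clipped_mol_m2": clipped,
            "relative_closure_error": closure,
        },
        "picard": {
            "max": max(picard_counts, default=0),
            "mean": float(np.mean(picard_counts)) if picard_counts else 0.0,
        },
        "transfer": {"Re": ctx.tc.Re, "Pr": ctx.tc.Pr, "Sc": ctx.tc.Sc,
                     "hT_W_m2K": ctx.tc.hT, "hm_m_s": ctx.tc.hm},
        "n_cells": ctx.n_cells,
        "dt_s": settings.dt,
    }
    return DryingCurve(t_min=np.array(times), mr=np.array(mrs),
                       T_center=np.array(t_center), T_mean=np.array(t_mean),
                       flux=np.array(fluxes), meta=meta)


def independence_study(comp: props.Composition, geometry: SampleGeometry,
                       conditions: DryingConditions,
                       settings: SolverSettings | None = None,
                       grid_levels: tuple[int, ...] = (15, 31, 61, 121),
                       dt_levels: tuple[float, ...] = (300.0, 120.0, 60.0),
                       probe_time_min: float = 60.0) -> dict:
    """Grid and time-step refinement report at a fixed probe time.

    A level is flagged converged when the probed MR changes by less than
    0.5 % from the previous (coarser) level.
    """
    if len(grid_levels) < 3 or len(dt_levels) < 3:
        raise ValueError("need at least three refinement levels each")
    settings = settings or SolverSettings()

    def probe(geom, stg):
        curve = simulate(comp, geom, conditions, stg)
        return float(np.interp(probe_time_min, curve.t_min, curve.mr))

    report = {"probe_time_min": probe_time_min, "grid": [], "dt": []}
    prev = None
    for n_z in grid_levels:
        mr = probe(replace(geometry, n_z=n_z), settings)
        rel = abs(mr - prev) / abs(prev) if prev is not None else np.inf
        report["grid"].append({"n_z": n_z, "mr": mr,
                               "rel_change": rel, "converged": rel < 5e-3})
        prev = mr
    prev = None
    for dt in dt_levels:
        mr = probe(geometry, replace(settings, dt=dt))
        rel = abs(mr - prev) / abs(prev) if prev is not None else np.inf
        report["dt"].append({"dt_s": dt, "mr": mr,
                             "rel_change": rel, "converged": rel < 5e-3})
        prev = mr
    return report
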