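"""Thermophysical properties of the drying sample.

Composition- and temperature-dependent mixture properties (density, specific
heat, thermal conductivity), moisture thermodynamics (water activity,
saturation state, wet/dry-basis conversions), pore-structure relations
(porosity, saturations, relative permeabilities, effective gas diffusivity)
and the effective thermal properties of the porous solid + pore-fluid
mixture.  This module is the coefficient factory for the drying simulator.

Component property polynomials are the standard food-component correlations
(Choi & Okos family), shipped as a plain-text data table so users can
override individual coefficients.  Mixture rules:

    rho = 1 / sum_i(x_i / rho_i(T))              (mass fractions x_i)
    cp  = sum_i(cp_i(T) * x_i)
    k   = sum_i(k_i(T) * E_i),   E_i = (x_i/rho_i) / sum_j(x_j/rho_j)
"""
from __future__ import annotations

import csv
from dataclasses import dataclass, field, fields
from importlib import resources
from typing import NamedTuple

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "CONSTANTS",
    "Composition",
    "ComponentPropertyModel",
    "ComponentTable",
    "PropertyBundle",
    "PropertyRangeError",
    "INJERA_COMPOSITION",
    "REFERENCE_PROPERTIES",
    "component_table",
    "mixture_density",
    "mixture_specific_heat",
    "mixture_conductivity",
    "volume_fractions",
    "porosity",
    "water_activity",
    "equilibrium_moisture",
    "saturation_state",
    "wet_basis_to_concentration",
    "concentration_to_wet_basis",
    "concentration_to_dry_basis",
    "dry_basis_to_concentration",
    "effective_gas_diffusivity",
    "permeabilities",
    "irreducible_saturation",
    "effective_thermal_props",
    "effective_thermal_mixture",
    "evaluate_bundle",
]


class PropertyRangeError(ValueError):
    """An input lies outside the validity range of a property model."""


@dataclass(frozen=True)
class PhysicalConstants:
    """Module-level record of the physical constants used throughout."""

    R: float = 8.314          # universal gas constant, J/(mol K)
    M_WATER: float = 0.018    # molar mass of water, kg/mol
    M_VAPOUR: float = 0.018   # molar mass of water vapour, kg/mol
    H_EVAP: float = 2.454e6   # latent heat of evaporation, J/kg
    D_WA: float = 2.6e-5      # water-air diffusivity, m^2/s
    D_VA: float = 2.6e-5      # vapour-air diffusivity, m^2/s
    RHO_WATER: float = 998.0  # liquid water density, kg/m^3
    CP_WATER: float = 1000.0  # pore-fluid water heat capacity, J/(kg K)
    K_WATER: float = 0.59     # liquid water conductivity, W/(m K)
    MU_WATER: float = 1.002e-3
    RHO_AIR: float = 1.25
    CP_AIR: float = 1000.0
    K_AIR: float = 0.0285
    MU_AIR: float = 1.81e-5


CONSTANTS = PhysicalConstants()

#: Measured reference values for fresh injera, used for soft validation
#: reports only (the mixture correlations do not reproduce cp and k).
REFERENCE_PROPERTIES = {
    "density_323K_kg_m3": 1136.49,
    "density_333K_kg_m3": 1135.41,
    "specific_heat_323K_J_kgK": 3676.0,
    "conductivity_313K_W_mK": 0.3657,
    "conductivity_333K_W_mK": 0.3434,
}

_COMPONENTS = ("water", "carbohydrate", "protein", "fat", "fiber", "ash")


@dataclass(frozen=True)
class Composition:
    """Mass fractions of the sample components, wet basis (kg/kg).

    Fractions must each lie in [0, 1] and sum to within [0.98, 1.02]
    (proximate analyses routinely overshoot slightly); :meth:`normalized`
    rescales them to an exact unit sum, which every mixture rule uses.
    """

    water: float
    carbohydrate: float
    protein: float
    fat: float
    fiber: float
    ash: float

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"mass fraction {f.name}={v} outside [0, 1]")
        total = self.total()
        if not 0.98 <= total <= 1.02:
            raise ValueError(
                f"mass fractions sum to {total:.4f}, outside [0.98, 1.02]")

    def total(self) -> float:
        return sum(getattr(self, f.name) for f in fields(self))

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def normalized(self) -> "Composition":
        t = self.total()
        return Composition(**{k: v / t for k, v in self.as_dict().items()})


#: Proximate composition of fresh injera (g/g wet basis): moisture 60.8 %,
#: carbohydrate 31.26 %, protein 4.85 %, fiber 1.63 %, ash 1.83 %, fat 0.46 %.
INJERA_COMPOSITION = Composition(
    water=0.608, carbohydrate=0.3126, protein=0.0485,
    fat=0.0046, fiber=0.0163, ash=0.0183,
)


@dataclass(frozen=True)
class ComponentPropertyModel:
    """Polynomial property model for one component, t in deg C."""

    component: str
    coefficients: dict[str, tuple[float, ...]]  # property -> poly coeffs
    t_min_K: float = 273.15
    t_max_K: float = 473.15

    def evaluate(self, prop: str, T: float | np.ndarray) -> float | np.ndarray:
        T = np.asarray(T, dtype=float)
        if np.any(T < self.t_min_K) or np.any(T > self.t_max_K):
            raise PropertyRangeError(
                f"temperature outside [{self.t_min_K}, {self.t_max_K}] K "
                f"for component '{self.component}'")
        t = T - 273.15
        coeffs = self.coefficients[prop]
        out = np.zeros_like(t)
        for order, a in enumerate(coeffs):
            out = out + a * t**order
        return float(out) if out.ndim == 0 else out


class ComponentTable:
    """Per-component property polynomials loaded from a plain-text table."""

    def __init__(self, models: dict[str, ComponentPropertyModel]):
        self.models = models

    @classmethod
    def from_csv_text(cls, text: str) -> "ComponentTable":
        raw: dict[str, dict[str, dict[int, float]]] = {}
        for row in csv.DictReader(text.splitlines()):
            comp = row["component"]
            raw.setdefault(comp, {}).setdefault(row["property"], {})[
                int(row["order"])] = float(row["coefficient"])
        models = {}
        for comp, props in raw.items():
            coeffs = {
                p: tuple(c[i] for i in range(max(c) + 1))
                for p, c in props.items()
            }
            models[comp] = ComponentPropertyModel(comp, coeffs)
        return cls(models)

    def evaluate(self, component: str, prop: str, T) -> float | np.ndarray:
        if component not in self.models:
            raise KeyError(f"unknown component '{component}'")
        return self.models[component].evaluate(prop, T)


_DEFAULT_TABLE: ComponentTable | None = None


def component_table() -> ComponentTable:
    """The packaged default component property table (cached)."""
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        text = (resources.files("injeradry.data")
                / "component_properties.csv").read_text()
        _DEFAULT_TABLE = ComponentTable.from_csv_text(text)
    return _DEFAULT_TABLE


# ---------------------------------------------------------------------------
# mixture rules
# ---------------------------------------------------------------------------

def mixture_density(comp: Composition, T: float,
                    table: ComponentTable | None = None) -> float:
    """Sample density from the harmonic mass-fraction mixture rule, kg/m^3."""
    table = table or component_table()
    x = comp.normalized().as_dict()
    return 1.0 / sum(x[c] / table.evaluate(c, "density", T)
                     for c in _COMPONENTS if x[c] > 0)


def mixture_specific_heat(comp: Composition, T: float,
                          table: ComponentTable | None = None) -> float:
    """Mass-fraction weighted specific heat, J/(kg K)."""
    table = table or component_table()
    x = comp.normalized().as_dict()
    return sum(x[c] * table.evaluate(c, "specific_heat", T)
               for c in _COMPONENTS if x[c] > 0)


def volume_fractions(comp: Composition, T: float,
                     table: ComponentTable | None = None) -> dict[str, float]:
    """Component volume fractions E_i; they sum to 1 exactly."""
    table = table or component_table()
    x = comp.normalized().as_dict()
    v = {c: x[c] / table.evaluate(c, "density", T)
         for c in _COMPONENTS if x[c] > 0}
    total = sum(v.values())
    return {c: vi / total for c, vi in v.items()}


def mixture_conductivity(comp: Composition, T: float,
                         table: ComponentTable | None = None) -> float:
    """Volume-fraction weighted thermal conductivity, W/(m K)."""
    table = table or component_table()
    E = volume_fractions(comp, T, table)
    return sum(E[c] * table.evaluate(c, "conductivity", T) for c in E)


# ---------------------------------------------------------------------------
# moisture thermodynamics
# ---------------------------------------------------------------------------

def porosity(rho_solid: float, rho_bulk: float) -> float:
    """Porosity from solid and bulk densities, eps = 1 - rho_s/rho_b.

    The measured porosity may also be pinned directly in the run
    configuration, which is the default route (eps = 0.74).
    """
    if rho_solid <= 0 or rho_bulk <= 0:
        raise ValueError("densities must be positive")
    eps = 1.0 - rho_solid / rho_bulk
    if not 0.0 <= eps < 1.0:
        raise ValueError(
            f"porosity {eps:.4f} outside [0, 1); check density inputs")
    return eps


def water_activity(x_db: float | np.ndarray) -> float | np.ndarray:
    """Sorption-isotherm water activity as a function of dry-basis moisture.

    aw = exp(-0.0267 X^-1.656 + 0.0107 exp(-1.287 X) X^1.51), monotone
    increasing with aw(0+) -> 0 and aw(inf) -> 1.
    """
    x = np.asarray(x_db, dtype=float)
    if np.any(x <= 0):
        raise ValueError("dry-basis moisture must be positive")
    aw = np.exp(-0.0267 * x**-1.656 + 0.0107 * np.exp(-1.287 * x) * x**1.51)
    return float(aw) if aw.ndim == 0 else aw


def equilibrium_moisture(aw_target: float) -> float:
    """Dry-basis moisture at which the isotherm equals ``aw_target``."""
    if not 0.0 < aw_target < 1.0:
        raise ValueError("water activity target must be in (0, 1)")
    return brentq(lambda x: water_activity(x) - aw_target, 1e-6, 50.0)


def saturation_state(T: float | np.ndarray) -> tuple:
    """Saturation vapour pressure (Pa) and concentration (mol/m^3) at T.

    Six-term saturation-pressure correlation; valid 273.15-473.15 K.
    """
    T = np.asarray(T, dtype=float)
    if np.any(T < 273.15) or np.any(T > 473.15):
        raise PropertyRangeError("temperature outside [273.15, 473.15] K")
    p = np.exp(-5800.2206 / T + 1.3915 - 0.0486 * T
               + 4.176e-5 * T**2 - 1.445e-8 * T**3 + 6.546 * np.log(T))
    c = p / (CONSTANTS.R * T)
    if T.ndim == 0:
        return float(p), float(c)
    return p, c


# ---------------------------------------------------------------------------
# moisture bookkeeping conventions
#
# c (mol/m^3) is total moisture per sample volume.  Wet basis follows
# M_wb = c Mw / rho_p; dry basis uses the dry-matrix volume fraction,
# X_db = c Mw / ((1 - eps) rho_p), so the two stay proportional.
# ---------------------------------------------------------------------------

def wet_basis_to_concentration(m_wb: float, rho_p: float) -> float:
    """c = M_wb rho_p / Mw  (mol moisture per m^3 of sample)."""
    return m_wb * rho_p / CONSTANTS.M_WATER


def concentration_to_wet_basis(c: float | np.ndarray, rho_p: float):
    return np.asarray(c) * CONSTANTS.M_WATER / rho_p


def concentration_to_dry_basis(c, eps: float, rho_p: float):
    """X_db = c Mw / ((1 - eps) rho_p); raises if eps = 1."""
    if eps >= 1.0:
        raise ValueError("porosity must be < 1 for a dry-basis conversion")
    out = np.asarray(c, dtype=float) * CONSTANTS.M_WATER / ((1.0 - eps) * rho_p)
    return float(out) if out.ndim == 0 else out


def dry_basis_to_concentration(x_db, eps: float, rho_p: float):
    if eps >= 1.0:
        raise ValueError("porosity must be < 1 for a dry-basis conversion")
    out = np.asarray(x_db, dtype=float) * (1.0 - eps) * rho_p / CONSTANTS.M_WATER
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# pore structure
# ---------------------------------------------------------------------------

def effective_gas_diffusivity(eps: float, s_g, d_va: float | None = None):
    """Gas-phase effective diffusivity D = D_va eps^(3/4) Sg^(10/3)."""
    if not 0.0 < eps <= 1.0:
        raise ValueError("porosity must be in (0, 1]")
    d_va = CONSTANTS.D_VA if d_va is None else d_va
    s_g = np.asarray(s_g, dtype=float)
    if np.any(s_g < 0) or np.any(s_g > 1):
        raise ValueError("gas saturation must be in [0, 1]")
    out = d_va * eps**0.75 * s_g**(10.0 / 3.0)
    return float(out) if out.ndim == 0 else out


def permeabilities(s_w, s_ir: float):
    """Relative permeabilities (k_wr, k_gr) of water and gas.

    k_wr = ((Sw - Sir)/(1 - Sir))^3 above the irreducible saturation, else 0;
    k_gr = 1 - 1.1 Sw below Sw = 1/1.1, else 0.  Both clamped to [0, 1].
    """
    s_w = np.asarray(s_w, dtype=float)
    if np.any(s_w < 0) or np.any(s_w > 1):
        raise ValueError("water saturation must be in [0, 1]")
    if not 0.0 <= s_ir < 1.0:
        raise ValueError("irreducible saturation must be in [0, 1)")
    k_wr = np.clip(((s_w - s_ir) / (1.0 - s_ir)) ** 3, 0.0, 1.0)
    k_wr = np.where(s_w > s_ir, k_wr, 0.0)
    k_gr = np.clip(1.0 - 1.1 * s_w, 0.0, 1.0)
    if s_w.ndim == 0:
        return float(k_wr), float(k_gr)
    return k_wr, k_gr


def irreducible_saturation(eps: float, T0: float) -> float:
    """Irreducible liquid saturation, Sir = 2.88 (1/T0) (ln(1/eps))^0.48."""
    if not 0.0 < eps < 1.0:
        raise ValueError("porosity must be in (0, 1)")
    s = 2.88 / T0 * np.log(1.0 / eps) ** 0.48
    if s >= 1.0:
        raise ValueError(f"irreducible saturation {s:.3f} >= 1")
    return float(s)


# ---------------------------------------------------------------------------
# effective thermal properties of the porous mixture
# ---------------------------------------------------------------------------

class EffectiveThermalProps(NamedTuple):
    rho_cp_eff: float  # J/(m^3 K)
    k_eff: float       # W/(m K)
    rho_f: float       # pore-fluid density, kg/m^3
    cp_f: float        # pore-fluid heat capacity, J/(kg K)
    k_f: float         # pore-fluid conductivity, W/(m K)


def effective_thermal_props(comp: Composition, T: float, eps: float,
                            x_v: float, rule: str = "as_printed",
                            table: ComponentTable | None = None,
                            ) -> EffectiveThermalProps:
    """Effective volumetric heat capacity and conductivity of the sample.

    The pore fluid is a water/air blend by the vapour mass fraction x_v:
    k_f, rho_f, cp_f interpolate linearly from the water values (x_v = 0)
    to the air values (x_v = 1).

    Two mixture rules are provided.  ``as_printed`` keeps the source-form
    weighting (rho cp)_eff = rho_p cp_p - (1 - eps) rho_f cp_f and
    k_eff = eps k_p + (1 - eps) k_f.  ``corrected`` uses the physically
    conventional volume-fraction form (solid weighted by 1 - eps, plus
    sign): (rho cp)_eff = (1 - eps) rho_p cp_p + eps rho_f cp_f and
    k_eff = (1 - eps) k_p + eps k_f.
    """
    rho_p = mixture_density(comp, T, table)
    cp_p = mixture_specific_heat(comp, T, table)
    k_p = mixture_conductivity(comp, T, table)
    return effective_thermal_mixture(rho_p, cp_p, k_p, eps, x_v, rule)


def effective_thermal_mixture(rho_p: float, cp_p: float, k_p: float,
                              eps: float, x_v: float, rule: str = "as_printed",
                              ) -> EffectiveThermalProps:
    """The mixture algebra behind :func:`effective_thermal_props`."""
    if not 0.0 <= x_v <= 1.0:
        raise ValueError("vapour mass fraction must be in [0, 1]")
    C = CONSTANTS
    k_f = C.K_WATER - (C.K_WATER - C.K_AIR) * x_v
    rho_f = C.RHO_WATER - (C.RHO_WATER - C.RHO_AIR) * x_v
    cp_f = C.CP_WATER - (C.CP_WATER - C.CP_AIR) * x_v
    if rule == "as_printed":
        rho_cp = rho_p * cp_p - (1.0 - eps) * rho_f * cp_f
        k_eff = eps * k_p + (1.0 - eps) * k_f
    elif rule == "corrected":
        rho_cp = (1.0 - eps) * rho_p * cp_p + eps * rho_f * cp_f
        k_eff = (1.0 - eps) * k_p + eps * k_f
    else:
        raise ValueError(f"unknown mixture rule '{rule}'")
    return EffectiveThermalProps(rho_cp, k_eff, rho_f, cp_f, k_f)


# ---------------------------------------------------------------------------
# bundle
# ---------------------------------------------------------------------------

@dataclass
class PropertyBundle:
    """All property values at one thermodynamic state (c, T)."""

    rho_in: float
    cp_in: float
    k_in: float
    eps: float
    aw: float
    pv_sat: float
    cv_sat: float
    D_gas: float
    Sw: float
    Sg: float
    Sir: float
    kwr: float
    kgr: float
    rho_cp_eff: float
    k_eff: float
    rho_f: float
    cp_f: float
    k_f: float
    Xv: float
    m_wb: float
    x_db: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def evaluate_bundle(comp: Composition, T: float, c: float, eps: float = 0.74,
                    T0: float = 298.15, rule: str = "as_printed",
                    table: ComponentTable | None = None) -> PropertyBundle:
    """Evaluate the full property set at moisture concentration c and T."""
    C = CONSTANTS
    rho_p = mixture_density(comp, T, table)
    cp_p = mixture_specific_heat(comp, T, table)
    k_p = mixture_conductivity(comp, T, table)
    m_wb = float(concentration_to_wet_basis(c, rho_p))
    x_db = concentration_to_dry_basis(c, eps, rho_p)
    aw = water_activity(max(x_db, 1e-9))
    pv, cv = saturation_state(T)
    s_w = float(np.clip(c * C.M_WATER / (eps * C.RHO_WATER), 0.0, 1.0))
    s_g = 1.0 - s_w
    s_ir = irreducible_saturation(eps, T0)
    k_wr, k_gr = permeabilities(s_w, s_ir)
    # vapour mass share of the pore fluid: gas-space vapour vs liquid water
    m_vap = cv * C.M_VAPOUR * s_g
    m_liq = C.RHO_WATER * s_w
    x_v = m_vap / (m_vap + m_liq) if (m_vap + m_liq) > 0 else 1.0
    eff = effective_thermal_props(comp, T, eps, x_v, rule, table)
    return PropertyBundle(
        rho_in=rho_p, cp_in=cp_p, k_in=k_p, eps=eps, aw=float(aw),
        pv_sat=pv, cv_sat=cv,
        D_gas=effective_gas_diffusivity(eps, s_g),
        Sw=s_w, Sg=s_g, Sir=s_ir, kwr=k_wr, kgr=k_gr,
        rho_cp_eff=eff.rho_cp_eff, k_eff=eff.k_eff,
        rho_f=eff.rho_f, cp_f=eff.cp_f, k_f=eff.k_f, Xv=x_v,
        m_wb=m_wb, x_db=x_db,
    )
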