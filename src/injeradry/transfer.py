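"""Convective heat and mass transfer coefficients at the sample surface.

The external airflow is not resolved; its effect on the sample enters
through flat-plate correlations for the heat (hT) and mass (hm) transfer
coefficients, evaluated from the dimensionless groups of the channel air.
The laminar branch applies below Re = 5e5 and the turbulent branch above
(the standard assignment for these correlations).
"""
from __future__ import annotations

from dataclasses import dataclass

from .properties import CONSTANTS, saturation_state

__all__ = [
    "AirState",
    "TransferCoefficients",
    "dimensionless_numbers",
    "heat_transfer_coefficient",
    "mass_transfer_coefficient",
    "transfer_coefficients",
    "far_field_vapour_concentration",
]

RE_TRANSITION = 5e5


@dataclass(frozen=True)
class AirState:
    """State and transport properties of the drying air.

    Transport properties default to the dry-air constants used for the
    tunnel conditions; humidity affects only the far-field vapour
    concentration, not the transport properties.
    """

    T_air: float = 333.15        # K
    u_air: float = 0.5           # m/s
    RH: float = 11.0             # %
    p_atm: float = 101325.0      # Pa
    rho: float = CONSTANTS.RHO_AIR      # kg/m^3
    mu: float = CONSTANTS.MU_AIR        # Pa s
    cp: float = CONSTANTS.CP_AIR        # J/(kg K)
    k: float = CONSTANTS.K_AIR          # W/(m K)
    D: float = CONSTANTS.D_VA           # m^2/s

    def __post_init__(self) -> None:
        if not 0.0 <= self.RH <= 100.0:
            raise ValueError(f"relative humidity {self.RH} outside [0, 100] %")
        for name in ("T_air", "u_air", "p_atm", "rho", "mu", "cp", "k", "D"):
            if getattr(self, name) <= 0:
                raise ValueError(f"air property {name} must be positive")


@dataclass(frozen=True)
class TransferCoefficients:
    Re: float
    Pr: float
    Sc: float
    hT: float   # W/(m^2 K)
    hm: float   # m/s
    L: float    # characteristic length, m


def dimensionless_numbers(air: AirState, L: float) -> tuple[float, float, float]:
    """Reynolds, Prandtl and Schmidt numbers of the channel air."""
    if L <= 0:
        raise ValueError("characteristic length must be positive")
    if air.mu <= 0 or air.D <= 0:
        raise ValueError("viscosity and diffusivity must be positive")
    Re = air.rho * air.u_air * L / air.mu
    Pr = air.cp * air.mu / air.k
    Sc = air.mu / (air.rho * air.D)
    return Re, Pr, Sc


def heat_transfer_coefficient(Re: float, Pr: float, k_eff: float,
                              L: float) -> float:
    """Surface heat transfer coefficient hT, W/(m^2 K).

    Laminar (Re < 5e5): hT = 2 k_eff/L * 0.3387 Re^1/2 Pr^1/3
                             / (1 + (0.0468/Pr)^2/3)^1/3
    Turbulent:          hT = 2 k_eff/L * Pr^1/3 (0.037 Re^4/5 - 871)
    """
    if Re <= 0 or Pr <= 0:
        raise ValueError("Re and Pr must be positive")
    if Re < RE_TRANSITION:
        nu_half = (0.3387 * Re**0.5 * Pr**(1 / 3)
                   / (1 + (0.0468 / Pr)**(2 / 3))**(1 / 3))
    else:
        nu_half = Pr**(1 / 3) * (0.037 * Re**0.8 - 871.0)
        if nu_half <= 0:
            raise ValueError("turbulent correlation gave a non-positive hT")
    return 2.0 * k_eff / L * nu_half


def mass_transfer_coefficient(Re: float, Sc: float, D_air: float,
                              L: float) -> float:
    """Surface mass transfer coefficient hm = D/L (2 + 0.552 Re^1/2 Sc^1/3)."""
    if Re <= 0 or Sc <= 0:
        raise ValueError("Re and Sc must be positive")
    return D_air / L * (2.0 + 0.552 * Re**0.5 * Sc**(1 / 3))


def transfer_coefficients(air: AirState, L: float, k_eff: float,
                          area_factor: float = 1.0) -> TransferCoefficients:
    """Both film coefficients for a run, optionally area-enhanced.

    ``area_factor`` multiplies hT and hm identically; it models the
    enlargement of the exchange surface by the open pore structure of the
    sample relative to the projected flat plate, and preserves the
    heat/mass-transfer analogy.
    """
    Re, Pr, Sc = dimensionless_numbers(air, L)
    hT = area_factor * heat_transfer_coefficient(Re, Pr, k_eff, L)
    hm = area_factor * mass_transfer_coefficient(Re, Sc, air.D, L)
    return TransferCoefficients(Re=Re, Pr=Pr, Sc=Sc, hT=hT, hm=hm, L=L)


def far_field_vapour_concentration(air: AirState) -> float:
    """Vapour concentration of the bulk drying air, mol/m^3."""
    _, cv_sat = saturation_state(air.T_air)
    return air.RH / 100.0 * cv_sat
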