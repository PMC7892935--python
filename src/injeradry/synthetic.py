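"""Pseudo-experimental tunnel-dryer datasets.

Emulates the measurement structure of the drying experiments: ~100 g
sample on a balance with a continuous (per-minute) mass record and a
centre thermocouple read every 15 min with +/-1 K accuracy.  The truth
curve comes either from the PDE simulator or from a closed-form kinetics
model; additive Gaussian noise is seeded and reproducible.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import kinetics as kin
from . import simulator as sim
from .curve import DryingCurve
from .transfer import AirState

__all__ = ["ExperimentSpec", "generate_experiment", "generate_factorial"]


@dataclass(frozen=True)
class ExperimentSpec:
    """One synthetic tunnel-dryer run."""

    air: AirState = field(default_factory=AirState)
    sample_mass_g: float = 100.0
    initial_moisture_wb: float = 0.608      # kg water / kg sample
    mass_interval_min: float = 1.0
    temp_interval_min: float = 15.0
    mass_noise_sd_g: float = 0.1            # balance-grade
    temp_noise_sd_K: float = 1.0            # thermocouple accuracy +/-1 K
    mr_noise_sd: float = 0.01               # when generating in MR space
    duration_min: float | None = None       # default: until the truth ends
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.mass_noise_sd_g, self.temp_noise_sd_K,
               self.mr_noise_sd) < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if min(self.mass_interval_min, self.temp_interval_min) <= 0:
            raise ValueError("record intervals must be positive")


def _truth_curve(spec: ExperimentSpec, truth) -> DryingCurve:
    if truth == "simulate" or truth is None:
        conditions = sim.DryingConditions(air=spec.air)
        return sim.simulate(sim.props.INJERA_COMPOSITION,
                            sim.SampleGeometry(), conditions)
    kind, model, params = truth
    if kind != "kinetics":
        raise ValueError("truth must be 'simulate' or "
                         "('kinetics', model, params)")
    duration = spec.duration_min or 180.0
    t = np.arange(0.0, duration + 1e-9, spec.mass_interval_min)
    fn = kin.KINETIC_MODELS[model][0]
    mr = fn(t, *params)
    return DryingCurve(t_min=t, mr=np.clip(mr, 0.0, 1.05),
                       meta={"source": "synthetic", "truth_model": model,
                             "truth_params": list(params), "Me": 0.0})


def generate_experiment(spec: ExperimentSpec, truth="simulate",
                        noise_space: str = "mass"
                        ) -> tuple[DryingCurve, pd.DataFrame]:
    """Sample a truth curve on the instrument grid and add seeded noise.

    Returns the noisy drying curve (MR space) and the raw instrument
    table with columns t_min, mass_g, T_center_K (temperature only at
    its own interval, NaN elsewhere).  Noise is applied either to the
    balance record (``noise_space="mass"``, SD ``mass_noise_sd_g``) or
    directly to the moisture ratio (``"mr"``, SD ``mr_noise_sd``).
    With all noise SDs zero the output equals the truth at the sample
    times exactly.
    """
    if noise_space not in ("mass", "mr"):
        raise ValueError("noise_space must be 'mass' or 'mr'")
    rng = np.random.default_rng(spec.seed)
    base = _truth_curve(spec, truth)
    t_end = spec.duration_min or float(base.t_min[-1])
    t = np.arange(0.0, t_end + 1e-9, spec.mass_interval_min)
    mr_true = np.interp(t, base.t_min, base.mr)
    if noise_space == "mr" and spec.mr_noise_sd > 0:
        mr_true = np.clip(mr_true + rng.normal(0.0, spec.mr_noise_sd,
                                               size=mr_true.shape), 0.0, None)

    # mass bookkeeping: dry matter plus dry-basis moisture
    m_dry = spec.sample_mass_g * (1.0 - spec.initial_moisture_wb)
    x0 = spec.initial_moisture_wb / (1.0 - spec.initial_moisture_wb)
    me = float(base.meta.get("Me", 0.0))
    # map MR back to gravimetric dry-basis moisture through the endpoints
    x = me + (x0 - me) * mr_true
    mass = m_dry * (1.0 + x)
    if noise_space == "mass" and spec.mass_noise_sd_g > 0:
        mass_noisy = mass + rng.normal(0.0, spec.mass_noise_sd_g,
                                       size=mass.shape)
    else:
        mass_noisy = mass.copy()
    mass_noisy = np.maximum(mass_noisy, m_dry)

    # centre temperature at its own record interval
    t_temp = np.arange(0.0, t_end + 1e-9, spec.temp_interval_min)
    if base.T_center is not None:
        T_true = np.interp(t_temp, base.t_min, base.T_center)
    else:
        T_true = np.full_like(t_temp, np.nan)
    T_noisy = T_true.copy()
    if spec.temp_noise_sd_K > 0 and base.T_center is not None:
        T_noisy = T_true + rng.normal(0.0, spec.temp_noise_sd_K,
                                      size=T_true.shape)

    raw = pd.DataFrame({"t_min": t, "mass_g": mass_noisy})
    raw["T_center_K"] = np.nan
    raw.loc[raw["t_min"].isin(np.round(t_temp, 9)), "T_center_K"] = T_noisy

    curve = kin.moisture_ratio_series(
        t, mass_noisy, m_dry, me, m0=x0,
        meta={"source": "synthetic", "seed": spec.seed,
              "T_air_K": spec.air.T_air, "u_air_m_s": spec.air.u_air,
              "RH_pct": spec.air.RH})
    return curve, raw


def generate_factorial(T_levels=(323.15, 333.15), u_levels=(0.25, 0.5),
                       n_reps: int = 3, base_rate: float = 0.010,
                       T_effect: float = 0.002, u_effect: float = 0.001,
                       interaction: float = 0.0, noise_sd: float = 0.0005,
                       seed: int = 0) -> pd.DataFrame:
    """Replicate drying rates for a balanced two-factor design.

    Rates (1/min) follow an additive cell-means model: base + T_effect for
    the high temperature, + u_effect for the high velocity, + interaction
    in the high/high cell, + N(0, noise_sd).  Deterministic per seed.
    """
    if len(T_levels) < 2 or len(u_levels) < 2 or n_reps < 2:
        raise ValueError("need >= 2 levels per factor and >= 2 replicates")
    rng = np.random.default_rng(seed)
    rows = []
    for i, T in enumerate(sorted(T_levels)):
        for j, u in enumerate(sorted(u_levels)):
            mean = (base_rate + T_effect * i + u_effect * j
                    + interaction * (i * j))
            for rep in range(n_reps):
                rate = mean + (rng.normal(0.0, noise_sd) if noise_sd > 0
                               else 0.0)
                rows.append({"T": T, "u": u, "rep": rep, "rate": rate})
    return pd.DataFrame(rows)
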