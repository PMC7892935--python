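"""The drying curve container shared by the simulator, fitter and generator.

Time is in minutes throughout the kinetics layer (rate constants are
per-minute); the PDE solver works in seconds and converts at this boundary.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["DryingCurve"]


@dataclass
class DryingCurve:
    """Moisture-ratio time series with optional temperature channels.

    Invariants: times strictly increasing, MR(0) within [0.95, 1.05] and
    all MR within [0, 1.05].
    """

    t_min: np.ndarray
    mr: np.ndarray
    T_center: np.ndarray | None = None
    T_mean: np.ndarray | None = None
    flux: np.ndarray | None = None          # surface flux, mol/(m^2 s)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t_min = np.asarray(self.t_min, dtype=float)
        self.mr = np.asarray(self.mr, dtype=float)
        if self.t_min.shape != self.mr.shape:
            raise ValueError("time and moisture-ratio arrays differ in length")
        if len(self.t_min) < 2:
            raise ValueError("a drying curve needs at least two samples")
        if np.any(np.diff(self.t_min) <= 0):
            raise ValueError("times must be strictly increasing")
        if not 0.95 <= self.mr[0] <= 1.05:
            raise ValueError(f"initial moisture ratio {self.mr[0]:.3f} "
                             "outside [0.95, 1.05]")
        if np.any(self.mr < -1e-12) or np.any(self.mr > 1.05):
            raise ValueError("moisture ratio outside [0, 1.05]")
        self.meta.setdefault("time_unit", "min")

    def __len__(self) -> int:
        return len(self.t_min)

    def drying_time(self, mr_target: float) -> float:
        """First time (min) the curve reaches ``mr_target``, interpolated.

        Raises ValueError if the curve never gets there.
        """
        below = np.nonzero(self.mr <= mr_target)[0]
        if len(below) == 0:
            raise ValueError(f"curve never reaches MR = {mr_target}")
        i = below[0]
        if i == 0:
            return float(self.t_min[0])
        t0, t1 = self.t_min[i - 1], self.t_min[i]
        m0, m1 = self.mr[i - 1], self.mr[i]
        return float(t0 + (m0 - mr_target) / (m0 - m1) * (t1 - t0))

    def to_frame(self) -> pd.DataFrame:
        cols = {"t_min": self.t_min, "MR": self.mr}
        if self.T_center is not None:
            cols["T_center_K"] = self.T_center
        if self.T_mean is not None:
            cols["T_mean_K"] = self.T_mean
        if self.flux is not None:
            cols["flux_mol_m2_s"] = self.flux
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, meta: dict | None = None
                   ) -> "DryingCurve":
        return cls(
            t_min=df["t_min"].to_numpy(),
            mr=df["MR"].to_numpy(),
            T_center=df["T_center_K"].to_numpy() if "T_center_K" in df else None,
            T_mean=df["T_mean_K"].to_numpy() if "T_mean_K" in df else None,
            flux=df["flux_mol_m2_s"].to_numpy() if "flux_mol_m2_s" in df else None,
            meta=dict(meta or {}),
        )

    @classmethod
    def from_csv(cls, path, meta: dict | None = None) -> "DryingCurve":
        meta = dict(meta or {})
        meta.setdefault("source", "file")
        return cls.from_frame(pd.read_csv(path), meta)
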