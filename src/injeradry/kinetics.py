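"""Thin-layer drying kinetics, goodness of fit, diffusivity and ANOVA.

Three semi-empirical moisture-ratio models are fitted by nonlinear least
squares (time in minutes):

    henderson_pabis:  MR = a exp(-k t)
    two_term:         MR = b1 exp(-k1 t) + b2 exp(-k2 t)
    page:             MR = exp(-k t^n)

Model selection follows descending R^2 (square of the Pearson correlation
between observed and fitted series) and ascending RMSE, with ties at the
reported 4-decimal precision broken in favour of fewer parameters.

The effective moisture diffusivity uses the first-term Fickian slab
approximation: the log-linear slope k of ln MR against time (in seconds)
over the falling-rate window MR in [0.7, 0.05] gives Deff = k L^2 / pi^2
with L the half-thickness of the slab.

The factorial analysis of drying rates is a balanced two-factor
fixed-effects ANOVA with interaction, computed from first principles.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import curve_fit

from .curve import DryingCurve

__all__ = [
    "KineticsFit",
    "KINETIC_MODELS",
    "moisture_ratio",
    "moisture_ratio_series",
    "fit_kinetics",
    "goodness",
    "rank_models",
    "effective_diffusivity_slope",
    "drying_rate",
    "anova_two_way",
]


# ---------------------------------------------------------------------------
# moisture ratio
# ---------------------------------------------------------------------------

def moisture_ratio(m, m0: float, me: float):
    """MR = (M - Me) / (M0 - Me); any consistent moisture basis."""
    if m0 <= me:
        raise ValueError("initial moisture must exceed equilibrium moisture")
    return (np.asarray(m, dtype=float) - me) / (m0 - me)


def moisture_ratio_series(t_min, masses_g, m_dry_g: float, me: float,
                          m0: float | None = None,
                          meta: dict | None = None) -> DryingCurve:
    """Build a drying curve from a raw balance record.

    ``masses_g`` is the sample mass over time; dry-basis moisture is
    (mass - m_dry)/m_dry.  ``me`` and ``m0`` are equilibrium and initial
    dry-basis moisture; ``m0`` defaults to the first sample.  MR(0) = 1 by
    construction.
    """
    masses = np.asarray(masses_g, dtype=float)
    if m_dry_g <= 0:
        raise ValueError("dry mass must be positive")
    x = (masses - m_dry_g) / m_dry_g
    if m0 is None:
        m0 = float(x[0])
    mr = moisture_ratio(x, m0, me)
    meta = dict(meta or {})
    meta.setdefault("source", "file")
    meta.update(m_dry_g=m_dry_g, Me=me, Mo=m0)
    return DryingCurve(t_min=np.asarray(t_min, dtype=float),
                       mr=np.clip(mr, 0.0, None), meta=meta)


# ---------------------------------------------------------------------------
# kinetics models
# ---------------------------------------------------------------------------

def _henderson_pabis(t, a, k):
    return a * np.exp(-k * t)


def _two_term(t, b1, k1, b2, k2):
    return b1 * np.exp(-k1 * t) + b2 * np.exp(-k2 * t)


def _page(t, k, n):
    return np.exp(-k * t**n)


#: name -> (function, parameter names, starting values, bounds)
KINETIC_MODELS = {
    "henderson_pabis": (_henderson_pabis, ("a", "k"),
                        (1.0, 0.02), ([0.0, 0.0], [2.0, 1.0])),
    "two_term": (_two_term, ("b1", "k1", "b2", "k2"),
                 (0.7, 0.02, 0.3, 0.005),
                 ([0.0, 0.0, 0.0, 0.0], [2.0, 1.0, 2.0, 1.0])),
    "page": (_page, ("k", "n"), (0.02, 1.0), ([0.0, 0.1], [2.0, 3.0])),
}


@dataclass(frozen=True)
class KineticsFit:
    model: str
    params: dict[str, float]
    r2: float
    rmse: float
    n_obs: int

    @property
    def n_params(self) -> int:
        return len(self.params)

    def predict(self, t_min) -> np.ndarray:
        fn = KINETIC_MODELS[self.model][0]
        return fn(np.asarray(t_min, dtype=float), *self.params.values())


def goodness(y_obs, y_pred) -> tuple[float, float]:
    """(R^2, RMSE) between observed and predicted series.

    R^2 is the square of the Pearson correlation coefficient; RMSE is
    sqrt(mean squared difference).  Raises on zero variance.
    """
    obs = np.asarray(y_obs, dtype=float)
    pred = np.asarray(y_pred, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1:
        raise ValueError("observed and predicted series must match in length")
    if len(obs) < 2:
        raise ValueError("need at least two observations")
    if np.std(obs) == 0 or np.std(pred) == 0:
        raise ValueError("R^2 undefined for a zero-variance series")
    r = np.corrcoef(obs, pred)[0, 1]
    rmse = float(np.sqrt(np.mean((obs - pred) ** 2)))
    return float(r * r), rmse


def fit_kinetics(curve: DryingCurve, model: str) -> KineticsFit:
    """Least-squares fit of one thin-layer model to a drying curve."""
    if model not in KINETIC_MODELS:
        raise KeyError(f"unknown kinetics model '{model}'")
    fn, names, p0, bounds = KINETIC_MODELS[model]
    t, mr = curve.t_min, curve.mr
    if len(t) < len(names) + 2:
        raise ValueError(f"need at least {len(names) + 2} points to fit "
                         f"{model}")
    try:
        popt, _ = curve_fit(fn, t, mr, p0=p0, bounds=bounds, maxfev=20000)
    except RuntimeError as exc:
        raise RuntimeError(f"{model} fit did not converge: {exc}") from exc
    pred = fn(t, *popt)
    r2, rmse = goodness(mr, pred)
    return KineticsFit(model=model, params=dict(zip(names, popt)),
                       r2=r2, rmse=rmse, n_obs=len(t))


def rank_models(curve: DryingCurve,
                models: tuple[str, ...] = ("henderson_pabis", "two_term",
                                           "page")) -> list[KineticsFit]:
    """All fits, best first.

    Ordered by descending R^2 then ascending RMSE, both compared at 4
    decimals; remaining ties go to the model with fewer parameters.
    """
    fits = [fit_kinetics(curve, m) for m in models]
    if len(fits) < 3:
        raise ValueError("ranking needs at least three successful fits")
    return sorted(fits, key=lambda f: (-round(f.r2, 4), round(f.rmse, 4),
                                       f.n_params))


# ---------------------------------------------------------------------------
# effective diffusivity (slope method)
# ---------------------------------------------------------------------------

def effective_diffusivity_slope(curve: DryingCurve, half_thickness: float,
                                window: tuple[float, float] = (0.7, 0.05),
                                ) -> float:
    """Effective moisture diffusivity (m^2/s) from the falling-rate slope.

    Least-squares slope k of ln MR versus time in seconds over the window
    MR in [window[1], window[0]], then Deff = k L^2 / pi^2 with L the slab
    half-thickness.
    """
    if half_thickness <= 0:
        raise ValueError("half thickness must be positive")
    hi, lo = window
    mask = (curve.mr <= hi) & (curve.mr >= lo)
    if mask.sum() < 4:
        raise ValueError("fewer than 4 samples inside the fitting window; "
                         "has the curve reached MR < 0.2?")
    t_s = curve.t_min[mask] * 60.0
    slope = -np.polyfit(t_s, np.log(curve.mr[mask]), 1)[0]
    return float(slope * half_thickness**2 / np.pi**2)


def drying_rate(curve: DryingCurve, t_window_min: float = 60.0) -> float:
    """Mean moisture-removal rate |dMR/dt| (1/min) over the first hour.

    The response variable for the factorial temperature/velocity analysis.
    """
    mask = curve.t_min <= t_window_min
    if mask.sum() < 2:
        raise ValueError("curve too short for the rate window")
    t, mr = curve.t_min[mask], curve.mr[mask]
    return float((mr[0] - mr[-1]) / (t[-1] - t[0]))


# ---------------------------------------------------------------------------
# two-factor ANOVA
# ---------------------------------------------------------------------------

def anova_two_way(data: pd.DataFrame, factor_a: str = "T", factor_b: str = "u",
                  response: str = "rate") -> pd.DataFrame:
    """Balanced two-factor fixed-effects ANOVA with interaction.

    Sums of squares are computed from cell, marginal and grand means
    (first principles); F statistics use the within-cell mean square.
    The design must be balanced with >= 2 levels per factor and >= 2
    replicates per cell.
    """
    df = data[[factor_a, factor_b, response]].copy()
    counts = df.groupby([factor_a, factor_b], sort=True).size()
    a_levels = df[factor_a].nunique()
    b_levels = df[factor_b].nunique()
    if a_levels < 2 or b_levels < 2:
        raise ValueError("need at least two levels per factor")
    if len(counts) != a_levels * b_levels or counts.nunique() != 1:
        raise ValueError("unbalanced design: equal replication per cell "
                         "is required")
    n_rep = int(counts.iloc[0])
    if n_rep < 2:
        raise ValueError("need at least two replicates per cell")

    y = df[response].to_numpy(dtype=float)
    grand = y.mean()
    mean_a = df.groupby(factor_a)[response].mean()
    mean_b = df.groupby(factor_b)[response].mean()
    mean_ab = df.groupby([factor_a, factor_b])[response].mean()

    ss_a = b_levels * n_rep * float(((mean_a - grand) ** 2).sum())
    ss_b = a_levels * n_rep * float(((mean_b - grand) ** 2).sum())
    ss_cells = n_rep * float(((mean_ab - grand) ** 2).sum())
    ss_ab = ss_cells - ss_a - ss_b
    ss_tot = float(((y - grand) ** 2).sum())
    ss_err = ss_tot - ss_cells

    df_a = a_levels - 1
    df_b = b_levels - 1
    df_ab = df_a * df_b
    df_err = a_levels * b_levels * (n_rep - 1)
    ms_err = ss_err / df_err

    rows = []
    for name, ss, dof in ((factor_a, ss_a, df_a), (factor_b, ss_b, df_b),
                          (f"{factor_a}:{factor_b}", ss_ab, df_ab)):
        if ms_err > 0:
            f_stat = (ss / dof) / ms_err
            p = float(stats.f.sf(f_stat, dof, df_err))
        else:  # identical replicates everywhere
            f_stat, p = 0.0, 1.0
        rows.append({"term": name, "sum_sq": ss, "df": dof,
                     "F": f_stat, "p": p})
    rows.append({"term": "residual", "sum_sq": ss_err, "df": df_err,
                 "F": np.nan, "p": np.nan})
    return pd.DataFrame(rows).set_index("term")
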