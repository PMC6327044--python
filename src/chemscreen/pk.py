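"""In-vivo quantification: plasma half-life, tumor volume, growth inhibition.

Half-life comes from log-linear regression over the terminal phase of a
single-dose concentration-time series (noncompartmental; t1/2 = ln2/|k|).
Tumor volume uses the standard caliper ellipsoid formula 0.5 * W^2 * L,
and percent tumor-growth inhibition (TGI) compares treated and vehicle
volume gains from the randomization baseline:
TGI% = 100 * (1 - dT/dC).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class PKSeries:
    """Single-dose concentration-time profile."""

    times_h: np.ndarray
    concentrations: np.ndarray
    dose_mg_per_kg: float | None = None

    def __post_init__(self):
        t = np.asarray(self.times_h, dtype=float)
        c = np.asarray(self.concentrations, dtype=float)
        if t.shape != c.shape or t.ndim != 1:
            raise ValueError("times and concentrations must be matching 1-D arrays")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(c < 0):
            raise ValueError("concentrations must be nonnegative")
        object.__setattr__(self, "times_h", t)
        object.__setattr__(self, "concentrations", c)


@dataclass(frozen=True)
class HalfLifeFit:
    t_half_h: float
    k_per_h: float  # elimination slope of ln(conc) vs time (negative)
    intercept: float
    n_points: int
    r_squared: float


def fit_half_life(series: PKSeries, terminal_points: int = 3) -> HalfLifeFit:
    """Terminal half-life by log-linear regression on the last samples.

    Fits ln(concentration) against time over the final `terminal_points`
    samples; t1/2 = ln(2) / |slope|.  Raises if fewer than 3 usable
    terminal points exist, if any is zero, or if the slope is
    nonnegative (no elimination phase).
    """
    if terminal_points < 3:
        raise ValueError("need >= 3 terminal points")
    t = series.times_h[-terminal_points:]
    c = series.concentrations[-terminal_points:]
    if len(t) < 3:
        raise ValueError("series shorter than requested terminal window")
    if np.any(c <= 0):
        raise ValueError("terminal concentrations must be positive")
    res = stats.linregress(t, np.log(c))
    if res.slope >= 0:
        raise ValueError("terminal concentrations do not decline (slope >= 0)")
    return HalfLifeFit(
        t_half_h=float(np.log(2) / abs(res.slope)),
        k_per_h=float(res.slope),
        intercept=float(res.intercept),
        n_points=len(t),
        r_squared=float(res.rvalue**2),
    )


def tumor_volume(w_mm: float, l_mm: float) -> float:
    """Caliper tumor volume 0.5 * W^2 * L in mm^3.

    W is the short axis by convention: if the arguments arrive swapped
    (W > L), they are exchanged before evaluation.
    """
    if w_mm < 0 or l_mm < 0:
        raise ValueError("caliper measurements must be nonnegative")
    if w_mm > l_mm:
        w_mm, l_mm = l_mm, w_mm
    return 0.5 * w_mm**2 * l_mm


def load_tumor_series(df: pd.DataFrame) -> pd.DataFrame:
    """Attach volumes to a caliper table (animal_id, group, day, W_mm, L_mm)."""
    out = df.copy()
    out["volume_mm3"] = [tumor_volume(w, l) for w, l in zip(out["W_mm"], out["L_mm"])]
    return out


def tgi_percent(
    treated: pd.DataFrame,
    vehicle: pd.DataFrame,
    endpoint_day: float,
    baseline_day: float | None = None,
) -> float:
    """Percent tumor-growth inhibition at the endpoint.

    Each frame has columns (day, volume_mm3) with one row per animal and
    day; group means are taken at baseline (default: earliest common
    day, i.e. randomization) and endpoint, and

        TGI% = 100 * (1 - (mean_T_end - mean_T_0) / (mean_C_end - mean_C_0))

    Raises if vehicle tumors did not grow (dC <= 0).
    """
    if baseline_day is None:
        baseline_day = max(treated["day"].min(), vehicle["day"].min())

    def _mean_at(df, day):
        sel = df.loc[df["day"] == day, "volume_mm3"]
        if sel.empty:
            raise ValueError(f"no measurements at day {day}")
        return float(sel.mean())

    d_treated = _mean_at(treated, endpoint_day) - _mean_at(treated, baseline_day)
    d_vehicle = _mean_at(vehicle, endpoint_day) - _mean_at(vehicle, baseline_day)
    if d_vehicle <= 0:
        raise ValueError("vehicle group did not grow; TGI undefined")
    return 100.0 * (1.0 - d_treated / d_vehicle)


def compare_groups(treated: pd.DataFrame, vehicle: pd.DataFrame, day: float):
    """Two-sample t-test of endpoint volumes between groups (convenience)."""
    a = treated.loc[treated["day"] == day, "volume_mm3"]
    b = vehicle.loc[vehicle["day"] == day, "volume_mm3"]
    return stats.ttest_ind(a, b, equal_var=False)
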