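"""Volumetric rates from batch concentration time series.

Concentrations of lovastatin (LOV, mg/l), biomass (X, g/l), lactose
(LAC, g/l) and organic nitrogen (N, g/l) sampled over a shake-flask
batch are smoothed with cubic smoothing splines and differentiated
analytically to give volumetric formation/uptake rates.  The smoothing
penalty defaults to generalized cross-validation and can be overridden
(``lam=0`` switches to exact cubic-spline interpolation, which
reproduces polynomial records of degree <= 3 and their derivatives to
machine precision).

Sign convention: products (LOV, X) are reported as formation rates
(+d/dt); substrates (LAC, N) as uptake rates (-d/dt), so uptake is
nonnegative while the substrate falls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline, make_smoothing_spline

__all__ = [
    "ANALYTE_ROLES",
    "BatchTimeSeries",
    "RateSeries",
    "smooth_and_differentiate",
    "peak_rates",
]

#: role -> sign of d(concentration)/dt in the reported rate
ANALYTE_ROLES = {"LOV": "formation", "X": "formation", "LAC": "uptake", "N": "uptake"}

ANALYTE_UNITS = {"LOV": "mg/l", "X": "g/l", "LAC": "g/l", "N": "g/l"}


@dataclass
class BatchTimeSeries:
    """Batch concentrations versus time (hours); any analyte subset."""

    times: np.ndarray
    concentrations: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        for name, values in self.concentrations.items():
            values = np.asarray(values, dtype=float)
            if len(values) != len(self.times):
                raise ValueError(f"{name}: length mismatch with times")
            if np.any(values[np.isfinite(values)] < 0):
                raise ValueError(f"{name}: concentrations must be nonnegative")
            self.concentrations[name] = values

    @property
    def analytes(self):
        return list(self.concentrations)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"time_h": self.times})
        for name, values in self.concentrations.items():
            unit = ANALYTE_UNITS.get(name, "g/l").replace("/", "_")
            df[f"{name}_{unit}"] = values
        return df


@dataclass
class RateSeries:
    """Volumetric rates on an evaluation grid (per hour units).

    ``rates[name]`` follows the sign convention of ANALYTE_ROLES;
    ``smoothed[name]`` holds the smoothed concentrations on the same
    grid (negative values clipped to zero for reporting).
    ``boundary`` flags the first and last grid points, where one-sided
    spline derivatives are less reliable.
    """

    times: np.ndarray
    rates: dict[str, np.ndarray]
    smoothed: dict[str, np.ndarray]
    boundary: np.ndarray
    splines: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"time_h": self.times})
        for name, values in self.rates.items():
            role = ANALYTE_ROLES.get(name, "formation")
            unit = ANALYTE_UNITS.get(name, "g/l")
            df[f"r_{name}_{unit.replace('/', '_')}_h"] = values
            df[f"r_{name}_role"] = role
        return df


def smooth_and_differentiate(
    series: BatchTimeSeries,
    lam: float | dict | None = None,
    grid_step_h: float = 1.0,
) -> RateSeries:
    """Cubic-smoothing-spline rates for every analyte in the record.

    Parameters
    ----------
    series : BatchTimeSeries
        At least 4 time points per analyte.
    lam : float, dict or None
        Smoothing penalty; None selects it by generalized
        cross-validation per analyte, a dict gives per-analyte control,
        and 0 means interpolation with a not-a-knot cubic spline.
    grid_step_h : float
        Spacing of the evaluation grid (hours).

    Returns
    -------
    RateSeries with analytic spline derivatives; uptake analytes carry
    the -d/dt sign so that a falling substrate has a positive rate.
    """
    t = series.times
    if len(t) < 4:
        raise ValueError(f"need at least 4 time points, got {len(t)}")
    grid = np.arange(t[0], t[-1] + 0.5 * grid_step_h, grid_step_h)
    grid = np.clip(grid, t[0], t[-1])
    rates: dict[str, np.ndarray] = {}
    smoothed: dict[str, np.ndarray] = {}
    splines: dict = {}
    for name, values in series.concentrations.items():
        ok = np.isfinite(values)
        if np.sum(ok) < 4:
            continue
        ti, yi = t[ok], values[ok]
        lam_i = lam.get(name) if isinstance(lam, dict) else lam
        if lam_i == 0:
            spl = CubicSpline(ti, yi)  # not-a-knot: exact for cubics
        else:
            spl = make_smoothing_spline(ti, yi, lam=lam_i)
        deriv = spl.derivative()(grid)
        sign = -1.0 if ANALYTE_ROLES.get(name) == "uptake" else 1.0
        rates[name] = sign * deriv
        smoothed[name] = np.clip(spl(grid), 0.0, None)
        splines[name] = spl
    boundary = np.zeros(len(grid), dtype=bool)
    boundary[[0, -1]] = True
    return RateSeries(times=grid, rates=rates, smoothed=smoothed, boundary=boundary, splines=splines)


def peak_rates(rate_series: RateSeries) -> dict[str, dict]:
    """Time and value of the maximum rate per analyte.

    Ties are broken toward the earlier time; a maximum at either record
    edge is flagged ``boundary_maximum`` because edge derivatives are
    one-sided.
    """
    if len(rate_series.times) == 0 or not rate_series.rates:
        raise ValueError("rate series is empty")
    out: dict[str, dict] = {}
    for name, values in rate_series.rates.items():
        if not np.any(np.isfinite(values)):
            continue
        i = int(np.nanargmax(values))  # argmax returns the first (earliest) maximum
        out[name] = {
            "time_h": float(rate_series.times[i]),
            "value": float(values[i]),
            "unit": f"{ANALYTE_UNITS.get(name, 'g/l')}/h",
            "boundary_maximum": bool(rate_series.boundary[i]),
        }
    return out
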