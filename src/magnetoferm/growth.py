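"""Growth, consumption, yield, productivity and magnetic-response analytics.

Operates on fermentation time series (dense simulator output or sparse noisy
at-line observations).  Specific growth rates are log-linear regression
slopes over a declared main-growth window; substrate consumption rates are
window slopes normalized by the time-averaged OD565, in mM/h per OD unit.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "RateEstimate",
    "YieldEstimate",
    "fit_growth_rate",
    "doubling_time",
    "consumption_rate",
    "yield_per_substrate",
    "magnetite_productivity",
    "cmag",
    "pool_estimates",
    "detect_growth_window",
    "MAGNETITE_PER_IRON",
]

#: M(Fe3O4) / (3 * M(Fe)): mg magnetite per mg magnetosome-bound iron.
MAGNETITE_PER_IRON = 231.531 / (3 * 55.845)


@dataclass
class RateEstimate:
    """A fitted rate with its replicate spread and provenance window."""

    value: float
    sd: float
    window: tuple[float, float]
    n_points: int

    def __post_init__(self) -> None:
        if self.window[0] >= self.window[1]:
            raise ValueError("window must satisfy start < end")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")
        if not math.isfinite(self.value):
            raise ValueError("estimate must be finite")


@dataclass
class YieldEstimate:
    """Biomass yield per substrate, with the OD->dry-weight conversion used."""

    value: float            # mg dry weight per mmol
    substrate: str
    od_to_dw: float         # g/L per OD565, recorded for provenance

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError("yield must be non-negative")


def _window_mask(times: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    t0, t1 = window
    if t0 >= t1:
        raise ValueError(f"window start must precede end, got {window}")
    return (times >= t0) & (times <= t1)


def fit_growth_rate(
    times: np.ndarray, od: np.ndarray, window: tuple[float, float]
) -> RateEstimate:
    """Specific growth rate mu (1/h): slope of ln(OD565) vs time in window.

    Non-positive OD points are excluded with a warning; fewer than three
    usable points is an error.  ``sd`` is the standard error of the slope
    (replicate spread is obtained by pooling per-replicate estimates with
    :func:`pool_estimates`).
    """
    times = np.asarray(times, dtype=float)
    od = np.asarray(od, dtype=float)
    mask = _window_mask(times, window)
    t, x = times[mask], od[mask]
    bad = x <= 0
    if bad.any():
        warnings.warn(f"excluding {bad.sum()} non-positive OD point(s) in window")
        t, x = t[~bad], x[~bad]
    if len(t) < 3:
        raise ValueError(f"need >= 3 positive OD points in window, got {len(t)}")
    res = stats.linregress(t, np.log(x))
    return RateEstimate(float(res.slope), float(res.stderr), window, len(t))


def doubling_time(mu: float) -> float:
    """Doubling time ln(2)/mu in hours; requires mu > 0."""
    if mu <= 0:
        raise ValueError(f"doubling time undefined for mu <= 0 (got {mu})")
    return math.log(2.0) / mu


def consumption_rate(
    times: np.ndarray,
    conc: np.ndarray,
    od: np.ndarray,
    window: tuple[float, float],
) -> RateEstimate:
    """Specific consumption rate (mM/h per OD565).

    Negative of the least-squares slope of concentration vs time over the
    window, divided by the time-averaged OD565 in the window.  Negative
    results (apparent production) are floored at zero with a warning.
    """
    times = np.asarray(times, dtype=float)
    conc = np.asarray(conc, dtype=float)
    od = np.asarray(od, dtype=float)
    if np.any(conc < 0):
        raise ValueError("concentrations must be non-negative")
    mask = _window_mask(times, window)
    if mask.sum() < 3:
        raise ValueError(f"need >= 3 points in window, got {int(mask.sum())}")
    mean_od = float(np.mean(od[mask]))
    if mean_od <= 0:
        raise ValueError("time-averaged OD in window is zero")
    res = stats.linregress(times[mask], conc[mask])
    rate = -float(res.slope) / mean_od
    if rate < 0:
        warnings.warn("negative consumption rate floored at 0 (net production?)")
        rate = 0.0
    return RateEstimate(rate, float(res.stderr) / mean_od, window, int(mask.sum()))


def yield_per_substrate(
    delta_od: float, delta_substrate: float, od_to_dw: float, substrate: str = "lactate"
) -> YieldEstimate:
    """Biomass yield Y_x/s in mg dry weight per mmol substrate consumed.

    ``delta_substrate`` is the concentration drop in mM (= mmol/L) from start
    to end of growth; ``od_to_dw`` converts OD565 to g dry weight per liter.
    """
    if delta_substrate <= 0:
        raise ValueError("substrate consumption must be positive")
    if od_to_dw <= 0:
        raise ValueError("od_to_dw must be positive")
    value = max(delta_od, 0.0) * od_to_dw * 1000.0 / delta_substrate
    return YieldEstimate(value, substrate, od_to_dw)


def magnetite_productivity(
    iron: float,
    biomass: float,
    process_time: float,
    magnetite_fraction: float = 0.99,
) -> float:
    """Volumetric magnetite productivity (mg Fe3O4 per L per h).

    ``iron`` is the cellular iron content (mg per g dry weight), ``biomass``
    the dry-weight concentration (g/L), ``process_time`` the complete process
    duration (h).  ``magnetite_fraction`` is the share of intracellular iron
    assumed bound in magnetite (default 99%); the stoichiometric factor
    M(Fe3O4)/(3 M(Fe)) converts iron mass to magnetite mass.
    """
    if iron < 0 or biomass < 0:
        raise ValueError("iron and biomass must be non-negative")
    if process_time <= 0:
        raise ValueError("process_time must be positive")
    if not (0.0 < magnetite_fraction <= 1.0):
        raise ValueError("magnetite_fraction must lie in (0, 1]")
    return magnetite_fraction * iron * biomass * MAGNETITE_PER_IRON / process_time


def cmag(od_max: float, od_min: float) -> float:
    """Magnetic response: ratio of max/min scattering intensities minus 1.

    Cells are magnetically aligned perpendicular vs parallel to the photometer
    beam; 0 means magnetically unresponsive.
    """
    if od_min <= 0:
        raise ValueError("od_min must be positive")
    if od_max < od_min:
        raise ValueError("od_max < od_min: orientation swap suspected")
    return od_max / od_min - 1.0


def pool_estimates(estimates: list[RateEstimate]) -> RateEstimate:
    """Pool per-replicate estimates: mean value, sd across replicates."""
    if not estimates:
        raise ValueError("no estimates to pool")
    vals = np.array([e.value for e in estimates])
    sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
    return RateEstimate(float(np.mean(vals)), sd, estimates[0].window,
                        int(sum(e.n_points for e in estimates)))


def detect_growth_window(
    times: np.ndarray, od: np.ndarray, width: float = 6.0
) -> tuple[float, float]:
    """Max-slope window autodetection (alternative to the printed windows).

    Slides a window of ``width`` hours over the trace and returns the one
    maximizing the ln(OD) slope.
    """
    times = np.asarray(times, dtype=float)
    od = np.asarray(od, dtype=float)
    ok = od > 0
    times, od = times[ok], od[ok]
    if len(times) < 3:
        raise ValueError("too few positive points for window detection")
    best, best_slope = (times[0], times[0] + width), -np.inf
    starts = np.unique(times[times <= times[-1] - width])
    for t0 in starts:
        m = (times >= t0) & (times <= t0 + width)
        if m.sum() < 3:
            continue
        slope = stats.linregress(times[m], np.log(od[m])).slope
        if slope > best_slope:
            best, best_slope = (float(t0), float(t0 + width)), slope
    return best
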