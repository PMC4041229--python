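"""Specific growth rates from OD600 time series.

The specific growth rate μ (h⁻¹) is the slope of ln(OD600) against time
during exponential phase; for an exact exponential it equals the
two-point form ln(X_t/X_0)/t for any pair of points in the phase.  The
exponential window is detected automatically, and the assay's
zero-growth rule is applied: a culture whose OD never rises above 0.04,
or whose OD decreases over the test, is assigned μ = 0.

Window detection keeps every contiguous stretch of readings above a
quantification floor whose log-linear fit is almost perfectly straight
(R² ≥ 0.998 by default) and takes the *longest* such stretch.  Read
noise is additive in OD, hence huge on ln(OD) at low density, and the
entry into stationary phase bends the log curve; a max-slope criterion
rides the former (upward bias) while a lax R² gate admits the latter
(downward bias).  The strict-linearity/longest-window combination
suppresses both, and on an exact exponential it selects the full span.

Treated growth is expressed as a percentage of the no-solvent controls'
mean rate μ₀ (set at 100%), which is the response variable the EC50
estimation downstream consumes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "ODSeries",
    "GrowthFit",
    "RelativeGrowth",
    "detect_exponential_window",
    "fit_growth_rate",
    "relative_growth",
    "ZERO_GROWTH_OD",
]

#: OD600 ceiling below which a culture is scored as not having grown.
#: Doubles as the quantification floor for log-linear fitting: below it,
#: additive read noise dominates ln(OD).
ZERO_GROWTH_OD = 0.04
#: Minimum overall OD rise distinguishing drift from growth when the
#: final reading is below the first.
MIN_RISE_OD = 0.02
#: Default minimum R² for a window to count as log-linear.
DEFAULT_R2_MIN = 0.998


@dataclass(frozen=True)
class ODSeries:
    """One blank-corrected OD600 time course for a single culture tube.

    ``concentration`` is the solvent concentration in mmol L⁻¹ (0 for
    no-solvent controls; nominal scale above the solubility limit).
    Requires ≥ 3 strictly increasing time points; small negative ODs
    (≥ −0.05) are tolerated after blank subtraction.
    """

    species: str
    solvent: str
    concentration: float
    replicate: str
    times: np.ndarray  # hours
    od: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.od, dtype=float)
        if t.ndim != 1 or t.shape != y.shape:
            raise ValueError("times and od must be 1-D arrays of equal length")
        if t.size < 3:
            raise ValueError("an OD series needs at least 3 time points")
        if t[0] < 0:
            raise ValueError("times must start at or after 0 h")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(y < -0.05):
            raise ValueError("OD600 readings below -0.05 indicate a blanking problem")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "od", y)


@dataclass(frozen=True)
class GrowthFit:
    """A fitted specific growth rate.

    ``zero_growth`` marks cultures caught by the no-growth rule; for
    those μ is exactly 0 and the window is undefined.
    """

    mu: float  # h⁻¹
    window: tuple[float, float] | None  # (t_start, t_end), hours
    n_points: int
    fit_r2: float
    zero_growth: bool
    max_od: float


@dataclass(frozen=True)
class RelativeGrowth:
    """Treated growth as percent of the control mean μ₀."""

    concentration: float  # mmol L⁻¹ (aqueous, or nominal above solubility)
    percent_mu0: tuple[float, ...]  # per replicate
    mean_percent: float
    sd_percent: float | None
    mu0: float  # h⁻¹


def _window_stats(t: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Slope and R² of the least-squares line y ~ t."""
    tm, ym = t.mean(), y.mean()
    dt, dy = t - tm, y - ym
    sxx = float(dt @ dt)
    sxy = float(dt @ dy)
    syy = float(dy @ dy)
    slope = sxy / sxx
    if syy == 0.0:
        return slope, 1.0 if sxy == 0.0 else 0.0
    return slope, sxy * sxy / (sxx * syy)


def detect_exponential_window(
    series: ODSeries,
    min_points: int = 3,
    r2_min: float = DEFAULT_R2_MIN,
    od_floor: float = ZERO_GROWTH_OD,
) -> tuple[float, float] | None:
    """Locate the exponential phase of an OD time course.

    Scans every contiguous window of at least ``min_points`` readings
    with OD above ``od_floor`` and keeps those whose log-linear fit has
    positive slope and R² ≥ ``r2_min``.  The longest qualifying window
    is returned (log-linearity over the longest stretch is the
    signature of exponential phase); among equally long windows the
    steeper wins, then the earlier.  Returns ``None`` when no window
    qualifies — a legitimate outcome for non-growing cultures.
    """
    usable = series.od > od_floor
    idx = np.flatnonzero(usable)
    if idx.size < min_points:
        return None
    best: tuple[int, float, float, float, float] | None = None  # (len, slope, -t0, t0, t1)
    for seg in np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1):
        if seg.size < min_points:
            continue
        t, y = series.times[seg], np.log(series.od[seg])
        m = seg.size
        for i in range(m - min_points + 1):
            for j in range(i + min_points, m + 1):
                slope, r2 = _window_stats(t[i:j], y[i:j])
                if slope <= 0 or r2 < r2_min:
                    continue
                key = (j - i, slope, -t[i], t[i], t[j - 1])
                if best is None or key[:3] > best[:3]:
                    best = key
    if best is None:
        return None
    return (float(best[3]), float(best[4]))


def fit_growth_rate(
    series: ODSeries,
    window: tuple[float, float] | None = None,
    min_points: int = 3,
    r2_min: float = DEFAULT_R2_MIN,
    od_floor: float = ZERO_GROWTH_OD,
) -> GrowthFit:
    """Fit μ as the log-linear slope of OD600 within the exponential window.

    The zero-growth rule is applied first: μ = 0 when the OD never
    exceeds 0.04, when the trace decreases overall (final < initial and
    total rise < 0.02), or when no exponential window is found.
    Readings at or below ``od_floor`` inside the window are excluded;
    if fewer than ``min_points`` remain the culture is scored as zero
    growth.  On exact exponential data the fitted slope equals
    ln(X_t/X_0)/t for any point pair in the window.
    """
    od = series.od
    max_od = float(od.max())
    if max_od <= ZERO_GROWTH_OD:
        return GrowthFit(0.0, None, 0, 0.0, True, max_od)
    if od[-1] < od[0] and (max_od - od[0]) < MIN_RISE_OD:
        return GrowthFit(0.0, None, 0, 0.0, True, max_od)
    if window is None:
        window = detect_exponential_window(
            series, min_points=min_points, r2_min=r2_min, od_floor=od_floor
        )
        if window is None:
            return GrowthFit(0.0, None, 0, 0.0, True, max_od)
    t0, t1 = window
    mask = (series.times >= t0) & (series.times <= t1) & (od > od_floor)
    n = int(mask.sum())
    if n < min_points:
        return GrowthFit(0.0, None, n, 0.0, True, max_od)
    slope, r2 = _window_stats(series.times[mask], np.log(od[mask]))
    if slope <= 0:
        return GrowthFit(0.0, None, n, float(r2), True, max_od)
    return GrowthFit(float(slope), (float(t0), float(t1)), n, float(r2), False, max_od)


def relative_growth(
    treated: Sequence[GrowthFit],
    controls: Sequence[GrowthFit],
    concentration: float = 0.0,
) -> RelativeGrowth:
    """Express treated replicate growth rates as percent of control μ₀.

    μ₀ is the mean rate over control replicates; each treated replicate
    is reported as 100·μ/μ₀, with the mean and sample SD across
    replicates.  All controls failing to grow invalidates the assay.
    """
    if not controls:
        raise ValueError("at least one no-solvent control is required")
    if not treated:
        raise ValueError("at least one treated replicate is required")
    mu0 = float(np.mean([c.mu for c in controls]))
    if mu0 <= 0:
        raise ValueError("all no-solvent controls scored zero growth; assay invalid")
    percents = tuple(100.0 * f.mu / mu0 for f in treated)
    mean = float(np.mean(percents))
    sd = float(np.std(percents, ddof=1)) if len(percents) >= 2 else None
    return RelativeGrowth(concentration, percents, mean, sd, mu0)
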