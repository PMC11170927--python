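"""Season segmentation from the annual temperature cycle.

A year of monthly mean temperatures is fitted with a single degree-5
least-squares polynomial over month index 1..12; the first derivative of
the fitted curve gives the temperature change rate through the year.
The month interval containing the derivative maximum is the fastest
rise, the interval containing the minimum is the fastest fall, and the
calendar is partitioned into early cool / warm / late cool seasons at
those two boundaries.  For the site climatology shipped with the
synthetic-data module the fastest rise falls between February and March
and the fastest fall between September and October, giving the
Jan-Feb / Mar-Sep / Oct-Dec partition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["AnnualCurve", "SeasonPartition", "fit_annual_curve", "derive_partition",
           "EARLY_COOL", "WARM", "LATE_COOL"]

EARLY_COOL = "early_cool"
WARM = "warm"
LATE_COOL = "late_cool"

_GRID_STEP = 0.01  # month resolution for locating derivative extrema


@dataclass
class AnnualCurve:
    """Degree-5 polynomial fit to 12 monthly temperatures."""

    poly: np.polynomial.Polynomial
    residuals: np.ndarray
    degenerate: bool        # constant (no seasonality) input
    underdetermined: bool   # fewer than 7 distinct values

    def __call__(self, t):
        return self.poly(t)

    def derivative(self, t):
        return self.poly.deriv()(t)


@dataclass
class SeasonPartition:
    """Month -> season labels with the two boundary locations (month units)."""

    labels: dict            # month (1..12) -> season label
    rise: float             # location of fastest temperature rise
    fall: float             # location of fastest temperature fall
    rise_interval: tuple    # (month, month+1) bracketing the rise
    fall_interval: tuple    # (month, month+1) bracketing the fall

    def months(self, label: str) -> list:
        return [m for m, lab in sorted(self.labels.items()) if lab == label]


def fit_annual_curve(monthly_temperature) -> AnnualCurve:
    """Fit a degree-5 polynomial to exactly 12 monthly values (deg C)."""
    y = np.asarray(monthly_temperature, dtype=float)
    if y.shape != (12,):
        raise ValueError("exactly 12 monthly temperatures required")
    if not np.isfinite(y).all():
        raise ValueError("monthly temperatures must be finite")
    degenerate = bool(np.ptp(y) < 1e-9)
    underdetermined = len(np.unique(np.round(y, 9))) < 7
    x = np.arange(1, 13, dtype=float)
    poly = np.polynomial.Polynomial.fit(x, y, 5)
    residuals = y - poly(x)
    return AnnualCurve(poly=poly, residuals=residuals,
                       degenerate=degenerate, underdetermined=underdetermined)


def _interval(t: float) -> tuple:
    """Month interval (m, m+1) bracketing a boundary location t."""
    lo = int(np.floor(t))
    lo = min(max(lo, 1), 11)
    return (lo, lo + 1)


def derive_partition(curve: AnnualCurve, threshold_hint: float | None = None) -> SeasonPartition:
    """Partition the year at the derivative extrema of the fitted curve.

    The derivative is evaluated on a dense grid (0.01-month step); the
    argmax locates the fastest rise and the argmin the fastest fall.
    Months strictly before the (rounded) rise boundary are early cool,
    months from the rise through the fall are warm, and the remainder is
    the late cool season.  ``threshold_hint`` is accepted for interface
    compatibility but the partition is derivative-based.
    """
    if curve.degenerate:
        raise ValueError("degenerate (constant) annual curve has no seasons")
    grid = np.arange(1.0, 12.0 + _GRID_STEP / 2, _GRID_STEP)
    slope = curve.derivative(grid)
    t_rise = float(grid[np.argmax(slope)])
    t_fall = float(grid[np.argmin(slope)])
    if not t_rise < t_fall:
        raise ValueError("fastest rise does not precede fastest fall; "
                         "unsupported annual cycle orientation")
    # Boundary months at calendar-month resolution: the warm season
    # starts with the month just after the rise location, the late cool
    # season with the month just after the fall location.
    warm_start = int(round(t_rise + 0.5))
    late_start = int(round(t_fall + 0.5))
    warm_start = min(max(warm_start, 2), 11)
    late_start = min(max(late_start, warm_start + 1), 12)
    labels = {}
    for m in range(1, 13):
        if m < warm_start:
            labels[m] = EARLY_COOL
        elif m < late_start:
            labels[m] = WARM
        else:
            labels[m] = LATE_COOL
    return SeasonPartition(labels=labels, rise=t_rise, fall=t_fall,
                           rise_interval=_interval(t_rise), fall_interval=_interval(t_fall))
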