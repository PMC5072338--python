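"""Quantify the share of diurnal flux variation attributable to the clock.

For each flux the fitted smooth trend is reduced to its range (maximum
minus minimum of the GAMM-style predicted values) separately for the
entrainment window and the constant-conditions window.  The percentage of
clock-driven variation is

    pct = 100 * range_constant / range_entrainment

Nocturnal assimilation is fixed at zero, and because nocturnal conductance
and transpiration stay above zero during entrainment their minimum is
forced to zero as well ("zero floor"): this enlarges the entrainment range
and makes the percentage a conservative (under-)estimate.

A stricter recomputation restricts the constant-phase extrema to the 12 h
of the subjective day, discarding apparent variation that would fall in
the night of a normal diurnal cycle.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .trend_smoothing import SmoothFit

__all__ = [
    "RangeSummary",
    "phase_extrema",
    "clock_percentage",
    "subjective_day_percentage",
    "summarize_ranges",
]


@dataclass(frozen=True)
class RangeSummary:
    """Per-flux entrainment vs constant-phase extrema and clock percentage."""

    process: str  # carbon_assimilation | water_flux
    species: str
    scale: str  # leaf | ecosystem
    max_entrain: float
    min_entrain: float
    range_entrain: float
    max_const: float
    min_const: float
    range_const: float
    pct_clock: float


def _round2(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def phase_extrema(
    fit: SmoothFit,
    window: tuple[float, float] | np.ndarray,
    floor_at_zero: bool = False,
) -> tuple[float, float, float, float]:
    """Extrema of the fitted smooth over a time window.

    ``window`` is either a ``(t_start, t_end)`` pair (half-open on the
    right, closed if it reaches the grid end) or a boolean mask over the
    fit's grid.  Returns ``(max, min, se_at_max, se_at_min)`` of the fitted
    values; with ``floor_at_zero`` negative fitted values are cropped to 0
    before taking extrema (no flux has biological meaning below zero).
    """
    if isinstance(window, tuple):
        t0, t1 = window
        mask = (fit.grid_t >= t0) & (fit.grid_t <= t1)
    else:
        mask = np.asarray(window, dtype=bool)
    if not mask.any():
        raise ValueError("window selects no grid points")
    values = fit.fitted[mask]
    ses = fit.se_fitted[mask]
    if floor_at_zero:
        values = np.maximum(values, 0.0)
    i_max = int(np.argmax(values))
    i_min = int(np.argmin(values))
    return float(values[i_max]), float(values[i_min]), float(ses[i_max]), float(ses[i_min])


def clock_percentage(
    range_const: float,
    range_entrain: float | None = None,
    max_entrain: float | None = None,
    floor_entrain_min_to_zero: bool = False,
) -> float:
    """Percent clock-driven variation, rounded half-up to 2 decimals.

    With the zero floor the entrainment range is taken as the entrainment
    maximum (minimum forced to 0); otherwise the supplied range is used.
    """
    if floor_entrain_min_to_zero:
        if max_entrain is None:
            raise ValueError("zero-floor rule needs max_entrain")
        denom = float(max_entrain)
    else:
        if range_entrain is None:
            raise ValueError("range_entrain required when flooring is off")
        denom = float(range_entrain)
    if denom <= 0:
        raise ValueError("entrainment range must be positive")
    return _round2(100.0 * float(range_const) / denom)


def subjective_day_percentage(
    fit: SmoothFit,
    entrain_window: tuple[float, float],
    subjective_day_mask: np.ndarray,
    floor_entrain_min_to_zero: bool = True,
) -> float:
    """Clock percentage with constant-phase extrema from the subjective day.

    ``subjective_day_mask`` is a boolean mask over ``fit.grid_t`` marking
    constant-phase grid points that fall in the lit window of entrainment.
    """
    mask = np.asarray(subjective_day_mask, dtype=bool)
    if not mask.any():
        raise ValueError("subjective-day window is empty")
    mx_e, mn_e, _, _ = phase_extrema(fit, entrain_window, floor_at_zero=True)
    mx_c, mn_c, _, _ = phase_extrema(fit, mask, floor_at_zero=True)
    return clock_percentage(
        mx_c - mn_c,
        range_entrain=mx_e - mn_e,
        max_entrain=mx_e,
        floor_entrain_min_to_zero=floor_entrain_min_to_zero,
    )


def summarize_ranges(
    fit: SmoothFit,
    entrain_window: tuple[float, float],
    constant_window: tuple[float, float],
    process: str,
    species: str,
    scale: str,
    floor_entrain_min_to_zero: bool = True,
) -> RangeSummary:
    """Build a model-predicted range summary for one flux.

    The entrainment window is the final full diurnal cycle before the
    constant phase; fitted values are floored at zero (fluxes below zero
    lack biological meaning), and the zero-floor rule sets the entrainment
    minimum to 0 — both assimilation (dark assimilation is zero) and water
    fluxes (nocturnal conductance above zero by protocol convention).
    """
    mx_e, mn_e, _, _ = phase_extrema(fit, entrain_window, floor_at_zero=True)
    mx_c, mn_c, _, _ = phase_extrema(fit, constant_window, floor_at_zero=True)
    if floor_entrain_min_to_zero:
        mn_e = 0.0
    range_e = mx_e - mn_e
    range_c = mx_c - mn_c
    return RangeSummary(
        process=process,
        species=species,
        scale=scale,
        max_entrain=mx_e,
        min_entrain=mn_e,
        range_entrain=range_e,
        max_const=mx_c,
        min_const=mn_c,
        range_const=range_c,
        pct_clock=clock_percentage(
            range_c,
            range_entrain=range_e,
            max_entrain=mx_e,
            floor_entrain_min_to_zero=floor_entrain_min_to_zero,
        ),
    )
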