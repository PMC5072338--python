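"""Derive canopy fluxes from raw chamber and lysimeter measurements.

Net ecosystem exchange of an open chamber follows from the CO2 mass
balance between inlet and outlet air, and canopy transpiration from the
(negative) slope of the lysimeter mass trace, estimated with the same
penalized-spline smoother used for trend analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trend_smoothing import derivative_with_ci, fit_smooth

__all__ = ["ChamberSample", "nee_from_chamber", "transpiration_from_mass"]

WATER_DENSITY_KG_PER_L = 1.000


@dataclass(frozen=True)
class ChamberSample:
    """One open-chamber CO2 mass-balance record."""

    t_h: float
    flow_mol_s: float
    c_in: float  # umol mol-1
    c_out: float  # umol mol-1
    ground_area_m2: float = 2.0


def nee_from_chamber(sample):
    """Net canopy CO2 uptake (umol m-2 s-1, positive = uptake).

    ``flow * (c_in - c_out)`` converts molar air flow times the CO2 mole
    fraction depletion into a molar CO2 flux, normalized by ground area.
    Accepts a single :class:`ChamberSample` or a DataFrame with the same
    columns, returning a scalar or an array respectively.
    """
    if isinstance(sample, pd.DataFrame):
        flow = sample["flow_mol_s"].to_numpy(float)
        c_in = sample["c_in"].to_numpy(float)
        c_out = sample["c_out"].to_numpy(float)
        area = sample["ground_area_m2"].to_numpy(float)
    else:
        flow, c_in, c_out, area = sample.flow_mol_s, sample.c_in, sample.c_out, sample.ground_area_m2
    if np.any(np.asarray(flow) <= 0):
        raise ValueError("flow_mol_s must be positive")
    if np.any(np.asarray(area) <= 0):
        raise ValueError("ground_area_m2 must be positive")
    return flow * (np.asarray(c_in) - np.asarray(c_out)) / area


def transpiration_from_mass(
    mass: pd.DataFrame,
    basis_dim: int = 20,
    time_col: str = "t_h",
    mass_col: str = "mass_kg",
    per_area_m2: float | None = None,
) -> pd.DataFrame:
    """Canopy transpiration (l h-1) from a lysimeter mass trace.

    The mass series is smoothed with the penalized spline and transpiration
    taken as the negative first derivative (1 kg of water = 1 l).  Negative
    rates — possible near the window edges where the derivative is poorly
    constrained — are floored at zero and flagged.  ``per_area_m2``
    optionally adds a per-ground-area column in mm h-1.
    """
    if len(mass) < 10:
        raise ValueError("need at least 10 lysimeter samples")
    t = mass[time_col].to_numpy(float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("time must be strictly increasing")
    series = pd.DataFrame({"t": t, "value": mass[mass_col].to_numpy(float), "macrocosm_id": 0})
    fit = fit_smooth(
        series, basis_dim=min(basis_dim, len(mass) - 4), ar1=False, grid_size=len(mass)
    )
    fit = derivative_with_ci(fit)
    e_grid = -fit.deriv / WATER_DENSITY_KG_PER_L
    # report on the observation grid
    e = np.interp(t, fit.grid_t, e_grid)
    flagged = e < 0
    out = pd.DataFrame({time_col: t, "e_canopy": np.maximum(e, 0.0), "floored": flagged})
    if per_area_m2 is not None:
        out["e_mm_h"] = out["e_canopy"] / per_area_m2
    return out
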