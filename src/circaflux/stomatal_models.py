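"""Stomatal-conductance model families with an optional circadian oscillator.

Three empirical models relate stomatal conductance ``gs`` (mol m-2 s-1) to
net assimilation ``A`` (umol m-2 s-1) and environmental drivers:

* Ball-Berry:  gs = g0 + g1 * A * h_rel / Ca
* Leuning:     gs = g0 + g1 * A / ((Ca - Gamma) * (1 + D / D0))
* Medlyn:      gs = g0 + 1.6 * (1 + g1 / sqrt(D)) * A / Ca

where ``D`` is vapor pressure deficit (kPa), ``Ca`` the CO2 mole fraction at
the leaf surface (umol mol-1), ``h_rel`` relative humidity derived from D and
the saturation vapor pressure, ``Gamma`` the CO2 compensation point and
``D0`` an empirical humidity sensitivity.

Circadian regulation enters by letting the slope ``g1`` oscillate over time:

    g1(t) = g1m + g1a * sin(g1f * 2*pi*t/24 + g1p)

with ``t`` in hours since experiment onset, ``g1m`` the mean slope, ``g1a``
the amplitude (slope units), ``g1f`` a dimensionless frequency multiplier
(1 means a 24 h period) and ``g1p`` the phase in radians.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "OscillatorParams",
    "StomatalModelSpec",
    "DriverInputs",
    "FAMILIES",
    "MODEL_GRID",
    "esat",
    "oscillator_g1",
    "predict_gs",
    "spec_from_key",
]

FAMILIES = ("BallBerry", "Leuning", "Medlyn")

#: short registry labels used in reports: family key -> label
FAMILY_LABELS = {"Medlyn": "Med", "Leuning": "Leu", "BallBerry": "Bal"}
_LABEL_TO_FAMILY = {v: k for k, v in FAMILY_LABELS.items()}


@dataclass(frozen=True)
class OscillatorParams:
    """Sinusoidal modulation of the stomatal slope g1.

    Units of ``g1m`` and ``g1a`` are those of the host model's slope.
    ``t_origin`` shifts the time axis so that phase is referenced to
    experiment onset.
    """

    g1m: float
    g1a: float = 0.0
    g1f: float = 1.0
    g1p: float = 0.0
    t_origin: float = 0.0


@dataclass(frozen=True)
class StomatalModelSpec:
    """One cell of the 3 families x (g0?) x (oscillator?) model grid."""

    family: str
    include_g0: bool = False
    include_oscillator: bool = False
    #: family-specific fixed constants (Leuning: gamma_umol_mol, d0_kpa)
    fixed_constants: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown model family {self.family!r}; expected one of {FAMILIES}")

    @property
    def key(self) -> str:
        """Registry label, e.g. ``"Med+g0+Osc"``."""
        parts = [FAMILY_LABELS[self.family]]
        if self.include_g0:
            parts.append("g0")
        if self.include_oscillator:
            parts.append("Osc")
        return "+".join(parts)

    @property
    def n_params(self) -> int:
        """Structural parameter count: g0 (optional) plus slope terms.

        Without the oscillator the slope contributes one parameter (g1);
        with it the mean g1m is inherited and (g1a, g1p) are free.
        """
        n = 1 if self.include_g0 else 0
        n += 2 if self.include_oscillator else 1
        return n

    @property
    def param_names(self) -> tuple[str, ...]:
        names: list[str] = ["g0"] if self.include_g0 else []
        names += ["g1a", "g1p"] if self.include_oscillator else ["g1"]
        return tuple(names)


def spec_from_key(key: str, fixed_constants: Mapping[str, float] | None = None) -> StomatalModelSpec:
    """Build a spec from a registry label like ``"Leu+g0"`` or ``"Bal+Osc"``."""
    parts = key.split("+")
    family = _LABEL_TO_FAMILY.get(parts[0])
    if family is None:
        raise ValueError(f"unknown family label {parts[0]!r}")
    flags = set(parts[1:])
    unknown = flags - {"g0", "Osc"}
    if unknown:
        raise ValueError(f"unknown flags {sorted(unknown)} in key {key!r}")
    return StomatalModelSpec(
        family=family,
        include_g0="g0" in flags,
        include_oscillator="Osc" in flags,
        fixed_constants=dict(fixed_constants or {}),
    )


#: the complete 12-spec grid (3 families x 2 g0 options x 2 oscillator options)
MODEL_GRID: tuple[StomatalModelSpec, ...] = tuple(
    StomatalModelSpec(family=f, include_g0=g0, include_oscillator=osc)
    for f in FAMILIES
    for g0 in (False, True)
    for osc in (False, True)
)


@dataclass(frozen=True)
class DriverInputs:
    """Drivers of the stomatal models, as aligned arrays or scalars."""

    a_leaf: np.ndarray | float
    ca_umol_mol: np.ndarray | float
    vpd_kpa: np.ndarray | float
    tair_c: np.ndarray | float
    t_h: np.ndarray | float


def esat(t_c):
    """Saturation vapor pressure (kPa) by the Tetens formula."""
    t_c = np.asarray(t_c, dtype=float)
    if np.any(t_c <= -273.15):
        raise ValueError("temperature below absolute zero")
    return 0.61078 * np.exp(17.27 * t_c / (t_c + 237.3))


def oscillator_g1(osc: OscillatorParams, t_h):
    """Evaluate the oscillating slope g1 at time ``t_h`` (hours)."""
    t = np.asarray(t_h, dtype=float)
    return osc.g1m + osc.g1a * np.sin(osc.g1f * 2.0 * np.pi * (t - osc.t_origin) / 24.0 + osc.g1p)


# Leuning defaults; the CO2 compensation point and humidity sensitivity are
# rarely reported alongside fits, so they are fixed constants here.
DEFAULT_GAMMA_UMOL_MOL = 50.0
DEFAULT_D0_KPA = 1.5


def _slope_driver(spec: StomatalModelSpec, drivers: DriverInputs) -> np.ndarray:
    """The multiplier X such that gs = g0 + g1 * X for the given family.

    For the Medlyn family the slope enters as g0 + 1.6*A/Ca + g1 * X with
    X = 1.6*A/(Ca*sqrt(D)); the constant 1.6*A/Ca offset is returned
    separately by :func:`_slope_offset`.
    """
    a = np.asarray(drivers.a_leaf, dtype=float)
    ca = np.asarray(drivers.ca_umol_mol, dtype=float)
    d = np.asarray(drivers.vpd_kpa, dtype=float)
    if np.any(ca <= 0):
        raise ValueError("ca_umol_mol must be positive")
    if spec.family == "Medlyn":
        if np.any(d <= 0):
            raise ValueError("Medlyn form is singular at zero VPD")
        return 1.6 * a / (ca * np.sqrt(d))
    if spec.family == "Leuning":
        gamma = spec.fixed_constants.get("gamma_umol_mol", DEFAULT_GAMMA_UMOL_MOL)
        d0 = spec.fixed_constants.get("d0_kpa", DEFAULT_D0_KPA)
        if np.any(ca <= gamma):
            raise ValueError("Leuning form requires Ca > Gamma")
        return a / ((ca - gamma) * (1.0 + d / d0))
    # Ball-Berry: relative humidity from VPD, clipped to [0, 1]
    h_rel = np.clip(1.0 - d / esat(drivers.tair_c), 0.0, 1.0)
    return a * h_rel / ca


def _slope_offset(spec: StomatalModelSpec, drivers: DriverInputs) -> np.ndarray | float:
    """Slope-independent term of the gs prediction (Medlyn's 1.6*A/Ca)."""
    if spec.family == "Medlyn":
        a = np.asarray(drivers.a_leaf, dtype=float)
        ca = np.asarray(drivers.ca_umol_mol, dtype=float)
        return 1.6 * a / ca
    return 0.0


def predict_gs(
    spec: StomatalModelSpec,
    params: Sequence[float] | Mapping[str, float],
    drivers: DriverInputs,
    g1m: float | None = None,
):
    """Predict stomatal conductance for one model spec.

    ``params`` holds the free parameters in :attr:`StomatalModelSpec.param_names`
    order (or as a mapping).  For oscillator specs the mean slope ``g1m`` is a
    fixed input inherited from the matching non-oscillator fit and must be
    supplied via ``g1m``.
    """
    if isinstance(params, Mapping):
        values = [float(params[name]) for name in spec.param_names]
    else:
        values = [float(v) for v in params]
    if len(values) != len(spec.param_names):
        raise ValueError(
            f"spec {spec.key} expects params {spec.param_names}, got {len(values)} values"
        )
    it = iter(values)
    g0 = next(it) if spec.include_g0 else 0.0
    if spec.include_oscillator:
        if g1m is None:
            raise ValueError("oscillator specs require the inherited mean slope g1m")
        g1a, g1p = next(it), next(it)
        osc = OscillatorParams(g1m=g1m, g1a=g1a, g1f=1.0, g1p=g1p)
        g1 = oscillator_g1(osc, drivers.t_h)
    else:
        g1 = next(it)
    x = _slope_driver(spec, drivers)
    return g0 + _slope_offset(spec, drivers) + g1 * x


def medlyn_gs(a_leaf, ca_umol_mol, vpd_kpa, g0: float, g1):
    """Medlyn unified model with a possibly time-varying slope ``g1``.

    Convenience used by the synthetic generator; ``g1`` may be an array
    aligned with the drivers.
    """
    a = np.asarray(a_leaf, dtype=float)
    d = np.asarray(vpd_kpa, dtype=float)
    if np.any(d <= 0):
        raise ValueError("Medlyn form is singular at zero VPD")
    return g0 + 1.6 * (1.0 + np.asarray(g1) / np.sqrt(d)) * a / np.asarray(ca_umol_mol, dtype=float)


def _canonical_oscillator(g1a: float, g1p: float) -> tuple[float, float]:
    """Resolve the (g1a, g1p) reflection: amplitude >= 0, phase in [0, 2*pi)."""
    if g1a < 0:
        g1a, g1p = -g1a, g1p + math.pi
    return g1a, g1p % (2.0 * math.pi)
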