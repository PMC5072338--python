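"""Ecotron-like synthetic gas-exchange data with known circadian structure.

The generator emulates a macrocosm experiment: canopies are entrained for
several days under a diurnal cycle mimicking an average sunny August day in
Montpellier (Tair 28/19 degC max/min, VPD 1.7/0.5 kPa, square-wave PAR at
500 umol m-2 s-1 with a 12 h photoperiod), after which PAR, Tair and VPD are
held exactly constant for 48 h starting at solar noon.  Any ~24 h
oscillation surviving into the constant phase is, by construction,
endogenous ("circadian").

Fluxes carry a sinusoidal circadian modulation with a known amplitude at
the leaf level and a configurable dilution of that amplitude at the canopy
level, mirroring the expectation that shaded, less tightly entrained leaves
damp canopy-scale rhythms.  Bean (LAI 7.5) therefore receives a stronger
dilution than cotton (LAI 4.5).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .stomatal_models import OscillatorParams, medlyn_gs

__all__ = [
    "ProtocolConfig",
    "TrueParams",
    "SPECIES_DEFAULTS",
    "generate_environment",
    "simulate_fluxes",
    "simulate_lysimeter",
    "generate_dataset",
]

ENV_COLUMNS = ["t_h", "par", "tair_c", "vpd_kpa", "ca_umol_mol", "phase", "subjective_day"]
LEAF_COLUMNS = ["t_h", "species", "macrocosm_id", "a_leaf", "gs", "tleaf_c"]
CANOPY_COLUMNS = ["t_h", "species", "macrocosm_id", "a_canopy", "e_canopy", "mass_kg"]


@dataclass(frozen=True)
class ProtocolConfig:
    """Timing and driver extremes of the entrainment/constant protocol."""

    entrainment_days: int = 5
    constant_hours: float = 48.0
    step_h: float = 0.2  # 12 min sampling, matching the chamber multiplexer
    lights_on_h: float = 6.0  # clock time of lights-on during entrainment
    photoperiod_h: float = 12.0
    par_max: float = 500.0
    tair_max: float = 28.0
    tair_min: float = 19.0
    vpd_max: float = 1.7
    vpd_min: float = 0.5
    ca_umol_mol: float = 400.0
    solar_noon_h: float = 12.0

    def __post_init__(self) -> None:
        if self.entrainment_days < 1:
            raise ValueError("entrainment_days must be >= 1")
        if self.constant_hours < 0:
            raise ValueError("constant_hours must be >= 0")
        if self.step_h <= 0:
            raise ValueError("step_h must be positive")

    @property
    def constant_start_h(self) -> float:
        """Constant phase begins at solar noon after the entrainment days."""
        return 24.0 * self.entrainment_days + self.solar_noon_h

    @property
    def total_hours(self) -> float:
        return self.constant_start_h + self.constant_hours


@dataclass(frozen=True)
class TrueParams:
    """Ground truth for one simulated species.

    ``amax``/``alpha`` parameterize the light response of assimilation;
    ``osc`` is the circadian oscillator on the Medlyn slope g1 used to
    generate gs; ``amp_a`` and ``phase_a`` modulate assimilation with a
    relative 24 h sinusoid; ``dilution`` scales every circadian amplitude
    when moving from leaf to canopy; noise is additive Gaussian with AR(1)
    correlation ``ar1_rho`` at the sampling step.
    """

    amax: float = 22.0
    alpha: float = 0.055
    theta: float = 0.9  # convexity of the non-rectangular hyperbola
    g0: float = 0.02  # nocturnal/minimal conductance; keeps dark-time gs above zero
    # g1 rhythm peaks mid-morning (t mod 24 = 9 h), the assimilation rhythm
    # at subjective noon: stomatal and biochemical clocks are phase-shifted
    osc: OscillatorParams = field(
        default_factory=lambda: OscillatorParams(g1m=4.0, g1a=1.0, g1f=1.0, g1p=1.75 * np.pi)
    )
    amp_a: float = 0.20
    phase_a: float = 1.5 * np.pi
    noise_sd_leaf: float = 0.5  # umol m-2 s-1, on a_leaf
    noise_sd_gs: float = 0.008  # mol m-2 s-1, on gs
    noise_sd_canopy: float = 0.4  # umol m-2 s-1, on a_canopy
    noise_sd_e: float = 0.01  # l h-1, on e_canopy
    ar1_rho: float = 0.3
    dilution: float = 0.6
    canopy_area_m2: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.amp_a < 1.0):
            raise ValueError("amp_a must lie in [0, 1)")
        if not (0.0 < self.dilution <= 1.0):
            raise ValueError("dilution must lie in (0, 1]")
        if not (-1.0 < self.ar1_rho < 1.0):
            raise ValueError("ar1_rho must lie in (-1, 1)")
        for name in ("noise_sd_leaf", "noise_sd_gs", "noise_sd_canopy", "noise_sd_e"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


# Bean's denser canopy (LAI 7.5 vs 4.5) shades more leaves, diluting the
# canopy-scale rhythm more strongly than in cotton.
SPECIES_DEFAULTS: dict[str, TrueParams] = {
    "bean": TrueParams(amax=26.0, alpha=0.06, amp_a=0.20, dilution=0.48, seed=11),
    "cotton": TrueParams(amax=21.0, alpha=0.055, amp_a=0.27, dilution=0.69, seed=23),
}


def generate_environment(config: ProtocolConfig = ProtocolConfig()) -> pd.DataFrame:
    """Simulate the macrocosm drivers over entrainment plus constant phase.

    During entrainment PAR is a square wave (0 or ``par_max`` for the 12 h
    photoperiod) while Tair and VPD follow a 24 h sine peaking at solar noon
    and bottoming at midnight.  The constant phase freezes all drivers at
    their solar-noon values (PAR 500, Tair 28, VPD 1.7 by default).
    """
    n = int(round(config.total_hours / config.step_h)) + 1
    t = np.round(np.arange(n) * config.step_h, 9)
    hod = np.mod(t, 24.0)

    lights_on = config.lights_on_h
    lights_off = lights_on + config.photoperiod_h
    lit = (hod >= lights_on) & (hod < lights_off)

    # diurnal sine peaking at solar noon, minimum 12 h earlier (midnight)
    cyc = np.sin(2.0 * np.pi * (hod - config.solar_noon_h + 6.0) / 24.0)
    tair = 0.5 * (config.tair_max + config.tair_min) + 0.5 * (config.tair_max - config.tair_min) * cyc
    vpd = 0.5 * (config.vpd_max + config.vpd_min) + 0.5 * (config.vpd_max - config.vpd_min) * cyc
    tair = np.clip(tair, config.tair_min, config.tair_max)
    vpd = np.clip(vpd, config.vpd_min, config.vpd_max)
    par = np.where(lit, config.par_max, 0.0)

    if config.constant_hours > 0:
        constant = t >= config.constant_start_h
    else:
        constant = np.zeros_like(t, dtype=bool)
    par = np.where(constant, config.par_max, par)
    tair = np.where(constant, config.tair_max, tair)
    vpd = np.where(constant, config.vpd_max, vpd)

    return pd.DataFrame(
        {
            "t_h": t,
            "par": par,
            "tair_c": tair,
            "vpd_kpa": vpd,
            "ca_umol_mol": config.ca_umol_mol,
            "phase": np.where(constant, "constant", "entrainment"),
            "subjective_day": lit,
        }
    )


def _light_response(par, truth: TrueParams) -> np.ndarray:
    """Non-rectangular hyperbola light response of gross assimilation."""
    par = np.asarray(par, dtype=float)
    s = truth.alpha * par + truth.amax
    disc = s * s - 4.0 * truth.theta * truth.alpha * par * truth.amax
    return (s - np.sqrt(np.maximum(disc, 0.0))) / (2.0 * truth.theta)


def _ar1_noise(rng: np.random.Generator, n: int, sd: float, rho: float) -> np.ndarray:
    """Stationary AR(1) Gaussian noise with marginal standard deviation sd."""
    if sd == 0.0 or n == 0:
        return np.zeros(n)
    innov_sd = sd * np.sqrt(1.0 - rho * rho)
    e = np.empty(n)
    e[0] = rng.normal(0.0, sd)
    shocks = rng.normal(0.0, innov_sd, size=n - 1)
    for i in range(1, n):
        e[i] = rho * e[i - 1] + shocks[i - 1]
    return e


def simulate_fluxes(
    env: pd.DataFrame,
    truth: TrueParams,
    species: str = "bean",
    n_macrocosms: int = 3,
    leaf_step_h: float = 4.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate leaf spot measurements and continuous canopy fluxes.

    Leaf assimilation is the light response times a 24 h sinusoidal
    modulation; gs follows the Medlyn model with the oscillating slope.
    Canopy fluxes per unit ground area repeat the leaf-driven signal with
    every circadian amplitude multiplied by ``truth.dilution``; transpiration
    is converted to l h-1 per macrocosm by a diffusion-based water flux at
    the chamber VPD.
    """
    if env.empty:
        raise ValueError("env must be non-empty")
    rng = np.random.default_rng(truth.seed)

    def deterministic(df: pd.DataFrame, dilution: float) -> tuple[np.ndarray, np.ndarray]:
        t = df["t_h"].to_numpy(float)
        a_pot = _light_response(df["par"].to_numpy(float), truth)
        mod_a = 1.0 + dilution * truth.amp_a * np.sin(2.0 * np.pi * t / 24.0 + truth.phase_a)
        a = a_pot * mod_a
        osc = truth.osc
        g1 = osc.g1m + dilution * osc.g1a * np.sin(
            osc.g1f * 2.0 * np.pi * (t - osc.t_origin) / 24.0 + osc.g1p
        )
        d = np.maximum(df["vpd_kpa"].to_numpy(float), 1e-6)
        gs = medlyn_gs(a, df["ca_umol_mol"].to_numpy(float), d, truth.g0, g1)
        return a, gs

    t_all = env["t_h"].to_numpy(float)
    leaf_mask = np.abs(t_all / leaf_step_h - np.round(t_all / leaf_step_h)) < 1e-6
    env_leaf = env.loc[leaf_mask].reset_index(drop=True)
    if env_leaf.empty:
        env_leaf = env.iloc[:1].reset_index(drop=True)

    a_leaf0, gs0 = deterministic(env_leaf, dilution=1.0)
    leaf_frames = []
    for m in range(1, n_macrocosms + 1):
        a = a_leaf0 + _ar1_noise(rng, len(env_leaf), truth.noise_sd_leaf, truth.ar1_rho)
        # no carbon assimilation in the dark
        a = np.where(env_leaf["par"].to_numpy(float) == 0.0, 0.0, a)
        gs = gs0 + _ar1_noise(rng, len(env_leaf), truth.noise_sd_gs, truth.ar1_rho)
        leaf_frames.append(
            pd.DataFrame(
                {
                    "t_h": env_leaf["t_h"],
                    "species": species,
                    "macrocosm_id": m,
                    "a_leaf": a,
                    "gs": np.maximum(gs, 0.0),
                    "tleaf_c": env_leaf["tair_c"],  # no leaf-air decoupling simulated
                }
            )
        )
    leaf = pd.concat(leaf_frames, ignore_index=True)

    a_can0, gs_can0 = deterministic(env, dilution=truth.dilution)
    # water flux: E (l/h) = gs * D/P * Mw * 3600 * ground area, 1 l = 1 kg
    d = env["vpd_kpa"].to_numpy(float)
    e_can0 = gs_can0 * (d / 101.325) * 0.018 * 3600.0 * truth.canopy_area_m2
    canopy_frames = []
    for m in range(1, n_macrocosms + 1):
        a = a_can0 + _ar1_noise(rng, len(env), truth.noise_sd_canopy, truth.ar1_rho)
        e = np.maximum(e_can0 + _ar1_noise(rng, len(env), truth.noise_sd_e, truth.ar1_rho), 0.0)
        mass = simulate_lysimeter(
            e, env["t_h"].to_numpy(float), initial_mass=1200.0, noise_sd=0.0, seed=truth.seed + m
        )
        canopy_frames.append(
            pd.DataFrame(
                {
                    "t_h": env["t_h"],
                    "species": species,
                    "macrocosm_id": m,
                    "a_canopy": a,
                    "e_canopy": e,
                    "mass_kg": mass,
                }
            )
        )
    canopy = pd.concat(canopy_frames, ignore_index=True)
    return leaf, canopy


def simulate_lysimeter(
    e_canopy,
    t_h,
    initial_mass: float = 1200.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Lysimeter mass trace: initial mass minus integrated transpiration.

    ``e_canopy`` (l h-1) is integrated by the trapezoid rule on the grid
    ``t_h``; 1 l of water weighs 1 kg.  Optional Gaussian weighing noise is
    added per sample, deterministically for a given seed.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    e = np.asarray(e_canopy, dtype=float)
    t = np.asarray(t_h, dtype=float)
    if e.shape != t.shape:
        raise ValueError("e_canopy and t_h must be aligned")
    cum = np.concatenate([[0.0], np.cumsum(0.5 * (e[1:] + e[:-1]) * np.diff(t))])
    mass = initial_mass - cum
    if noise_sd > 0:
        mass = mass + np.random.default_rng(seed).normal(0.0, noise_sd, size=mass.shape)
    return mass


def generate_dataset(
    config: ProtocolConfig = ProtocolConfig(),
    species_params: dict[str, TrueParams] | None = None,
    seed: int | None = None,
    n_macrocosms: int = 3,
    leaf_step_h: float = 4.0,
) -> dict[str, pd.DataFrame]:
    """Full two-species dataset: environment plus leaf and canopy tables.

    ``seed`` (if given) offsets each species' own seed so that a single
    integer reproduces the whole dataset.
    """
    params = dict(species_params or SPECIES_DEFAULTS)
    env = generate_environment(config)
    leaves, canopies = [], []
    for i, (species, truth) in enumerate(sorted(params.items())):
        if seed is not None:
            truth = replace(truth, seed=(seed * 1009 + 97 * i) % (2**31 - 1))
        leaf, canopy = simulate_fluxes(
            env, truth, species=species, n_macrocosms=n_macrocosms, leaf_step_h=leaf_step_h
        )
        leaves.append(leaf)
        canopies.append(canopy)
    return {
        "env": env,
        "leaf": pd.concat(leaves, ignore_index=True),
        "canopy": pd.concat(canopies, ignore_index=True),
    }
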