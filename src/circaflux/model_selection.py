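"""Fitting, AIC-based comparison and calibration/validation of gs models.

Each of the twelve stomatal-model specs (three families, with and without
g0, with and without a circadian oscillator on the slope) is fitted to
observed leaf conductance by Gaussian maximum likelihood (equivalently
least squares).  Oscillator specs inherit their mean slope g1m from the
converged fit of the matching non-oscillator spec and only estimate the
amplitude g1a and phase g1p (plus g0 when included), with the frequency
fixed to a 24 h period.

Models are compared by AIC = -2 L(MLE) + 2 p and Akaike weights
w_i = exp(-dAIC_i / 2) / sum_j exp(-dAIC_j / 2).  Three
calibration/validation schemes mirror the experiment: fit and validate on
everything; fit under the changing (entrainment) day and validate under
constant conditions; and the reverse.  Fits are per species; validation
pools species before computing R2 of observed versus predicted.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from .stomatal_models import (
    MODEL_GRID,
    DriverInputs,
    StomatalModelSpec,
    _canonical_oscillator,
    _slope_driver,
    _slope_offset,
    predict_gs,
)

__all__ = [
    "FitResult",
    "SplitScheme",
    "SCHEMES",
    "fit_spec",
    "aic",
    "delta_aic",
    "akaike_weights",
    "validation_r2",
    "attach_drivers",
    "run_scheme",
    "run_all_schemes",
]

@dataclass
class FitResult:
    """One fitted spec: estimates, likelihood and comparison statistics."""

    spec: StomatalModelSpec
    estimates: dict  # name -> value
    standard_errors: dict  # name -> SE
    g1m: float | None
    loglik: float
    p: int
    n: int
    sse: float
    aic: float
    converged: bool = True
    delta_aic: float = float("nan")
    weight: float = float("nan")
    r2_validation: float = float("nan")
    scheme: str | None = None
    species: str | None = None


@dataclass(frozen=True)
class SplitScheme:
    """Calibration/validation split expressed as phase selectors.

    ``"all"`` selects every sample, ``"changing"`` the final entrainment
    day, ``"constant"`` the constant-conditions window.
    """

    name: str
    calibration_window: str
    validation_window: str


SCHEMES: dict[str, SplitScheme] = {
    "All->All": SplitScheme("All->All", "all", "all"),
    "Cha->Con": SplitScheme("Cha->Con", "changing", "constant"),
    "Con->Cha": SplitScheme("Con->Cha", "constant", "changing"),
}


def gaussian_loglik(sse: float, n: int) -> float:
    """Profile Gaussian log-likelihood at the MLE, sigma^2 = SSE/n.

    The variance is floored at 1e-24 (residuals at roundoff level) so that
    two models both fitting exactly are judged equal in likelihood rather
    than by meaningless ratios of accumulated floating-point error.
    """
    sigma2 = max(sse / n, 1e-24)
    return -0.5 * n * (math.log(2.0 * math.pi * sigma2) + 1.0)


def aic(loglik: float, p: int) -> float:
    """Akaike information criterion, -2 L(MLE) + 2 p."""
    return -2.0 * loglik + 2.0 * p


def delta_aic(aics) -> np.ndarray:
    """AIC differences to the smallest AIC in the compared set."""
    a = np.asarray(list(aics), dtype=float)
    if a.size == 0:
        raise ValueError("empty AIC set")
    return a - np.nanmin(a)


def akaike_weights(aics) -> np.ndarray:
    """Akaike weights: normalized relative likelihoods exp(-dAIC/2)."""
    d = delta_aic(aics)
    rel = np.exp(-0.5 * d)
    return rel / np.nansum(rel)


def validation_r2(observed, predicted) -> float:
    """R2 of the observed-versus-predicted regression (squared Pearson r)."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.size < 3:
        raise ValueError("need at least 3 observation/prediction pairs")
    if np.std(obs) == 0.0 or np.std(pred) == 0.0:
        warnings.warn("zero variance in observed or predicted values; R2 undefined")
        return float("nan")
    r = np.corrcoef(obs, pred)[0, 1]
    return float(r * r)


def _drivers_from_frame(df: pd.DataFrame) -> DriverInputs:
    return DriverInputs(
        a_leaf=df["a_leaf"].to_numpy(float),
        ca_umol_mol=df["ca_umol_mol"].to_numpy(float),
        vpd_kpa=df["vpd_kpa"].to_numpy(float),
        tair_c=df["tair_c"].to_numpy(float),
        t_h=df["t_h"].to_numpy(float),
    )


def fit_spec(
    spec: StomatalModelSpec,
    leaf_data: pd.DataFrame,
    g1m_source: FitResult | None = None,
) -> FitResult:
    """Fit one model spec to a leaf table by least squares.

    ``leaf_data`` must carry columns ``gs``, ``a_leaf``, ``ca_umol_mol``,
    ``vpd_kpa``, ``tair_c`` and ``t_h``.  Non-oscillator specs are linear in
    their parameters and solved exactly; oscillator specs fix g1m at the
    source fit's slope estimate, after which the sinusoid is linear in its
    in-phase/quadrature components and is likewise solved exactly.
    """
    df = leaf_data.dropna(subset=["gs", "a_leaf", "ca_umol_mol", "vpd_kpa", "tair_c", "t_h"])
    n = len(df)
    if n < spec.n_params + 2:
        raise ValueError(f"need at least {spec.n_params + 2} observations for {spec.key}, got {n}")
    drivers = _drivers_from_frame(df)
    gs_obs = df["gs"].to_numpy(float)
    x = _slope_driver(spec, drivers)
    y = gs_obs - np.asarray(_slope_offset(spec, drivers))

    if not spec.include_oscillator:
        cols = [x] if not spec.include_g0 else [np.ones(n), x]
        design = np.column_stack(cols)
        coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ coef
        sse = float(resid @ resid)
        sigma2 = sse / n
        cov = sigma2 * np.linalg.pinv(design.T @ design)
        ses = np.sqrt(np.diag(cov))
        names = spec.param_names
        estimates = dict(zip(names, map(float, coef)))
        standard_errors = dict(zip(names, map(float, ses)))
        g1m = None
        converged = True
    else:
        if g1m_source is None or "g1" not in g1m_source.estimates:
            raise ValueError("oscillator specs require a converged non-oscillator fit as g1m_source")
        g1m = float(g1m_source.estimates["g1"])
        # conditional on the inherited g1m, the sinusoid is linear in the
        # in-phase / quadrature pair (a, b) = g1a (cos g1p, sin g1p):
        #   g1(t) x = g1m x + a x sin(2 pi t/24) + b x cos(2 pi t/24)
        # so the MLE is an exact linear solve, no multi-start needed
        phase_arg = 2.0 * np.pi * drivers.t_h / 24.0
        xs = x * np.sin(phase_arg)
        xc = x * np.cos(phase_arg)
        cols = ([np.ones(n)] if spec.include_g0 else []) + [xs, xc]
        design = np.column_stack(cols)
        rhs = y - g1m * x
        coef, _, _, _ = np.linalg.lstsq(design, rhs, rcond=None)
        resid = rhs - design @ coef
        sse = float(resid @ resid)
        sigma2 = sse / n
        cov_lin = sigma2 * np.linalg.pinv(design.T @ design)
        i0 = 1 if spec.include_g0 else 0
        a, b_ = coef[i0], coef[i0 + 1]
        g1a, g1p = _canonical_oscillator(float(np.hypot(a, b_)), float(np.arctan2(b_, a)))
        vaa, vbb, vab = cov_lin[i0, i0], cov_lin[i0 + 1, i0 + 1], cov_lin[i0, i0 + 1]
        # conservative amplitude SE (joint (a, b) uncertainty): the delta
        # method collapses at the g1a = 0 null where the phase is free
        se_g1a = float(np.sqrt(max(vaa + vbb, 0.0)))
        r2_amp = max(g1a**2, 1e-300)
        se_g1p = float(
            np.sqrt(max(b_**2 * vaa - 2 * a * b_ * vab + a**2 * vbb, 0.0)) / r2_amp
        )
        estimates = {"g1a": float(g1a), "g1p": float(g1p)}
        standard_errors = {"g1a": se_g1a, "g1p": se_g1p}
        if spec.include_g0:
            estimates = {"g0": float(coef[0]), **estimates}
            standard_errors = {"g0": float(np.sqrt(max(cov_lin[0, 0], 0.0))), **standard_errors}
        converged = True
        # nesting: adding the (a, b) columns can only reduce the SSE below
        # the parent fit's, since (g0, a=0, b=0) reproduces it exactly
        if sse > g1m_source.sse + 1e-8 * max(g1m_source.sse, 1.0):
            converged = False
            warnings.warn(f"{spec.key}: oscillator fit worse than its g1a=0 null; flagged")

    ll = gaussian_loglik(sse, n)
    p = spec.n_params
    return FitResult(
        spec=spec,
        estimates=estimates,
        standard_errors=standard_errors,
        g1m=g1m,
        loglik=ll,
        p=p,
        n=n,
        sse=sse,
        aic=aic(ll, p),
        converged=converged,
    )


def attach_drivers(leaf: pd.DataFrame, env: pd.DataFrame) -> pd.DataFrame:
    """Join environmental drivers and phase labels onto a leaf table by t_h."""
    cols = [c for c in ("t_h", "par", "tair_c", "vpd_kpa", "ca_umol_mol", "phase") if c in env.columns]
    drop = [c for c in cols if c != "t_h" and c in leaf.columns]
    return leaf.drop(columns=drop).merge(env[cols], on="t_h", how="inner")


def _window_mask(df: pd.DataFrame, window: str, env: pd.DataFrame | None = None) -> np.ndarray:
    """Row selector for a phase window.

    ``changing`` is the final entrainment day (24 h preceding the constant
    phase); ``constant`` is the constant-conditions window.  Phase labels are
    taken from the ``phase`` column, joined from ``env`` on ``t_h`` if absent.
    """
    if window == "all":
        return np.ones(len(df), dtype=bool)
    if "phase" not in df.columns:
        if env is None:
            raise ValueError("phase labels unavailable; provide env")
        df = df.merge(env[["t_h", "phase"]], on="t_h", how="left")
    phase = df["phase"].to_numpy()
    t = df["t_h"].to_numpy(float)
    const_mask = phase == "constant"
    if window == "constant":
        return const_mask
    if window == "changing":
        t0 = t[const_mask].min() if const_mask.any() else t.max() + 1.0
        return (~const_mask) & (t >= t0 - 24.0)
    raise ValueError(f"unknown window {window!r}")


def _fit_grid_one_species(cal: pd.DataFrame, grid) -> dict[str, FitResult]:
    results: dict[str, FitResult] = {}
    ordered = sorted(grid, key=lambda s: s.include_oscillator)  # parents first
    for spec in ordered:
        source = None
        if spec.include_oscillator:
            parent = StomatalModelSpec(
                family=spec.family, include_g0=spec.include_g0, include_oscillator=False,
                fixed_constants=dict(spec.fixed_constants),
            )
            source = results[parent.key]
        results[spec.key] = fit_spec(spec, cal, g1m_source=source)
    return results


def run_scheme(
    scheme: SplitScheme,
    leaf_data: pd.DataFrame,
    env: pd.DataFrame | None = None,
    model_grid=MODEL_GRID,
) -> pd.DataFrame:
    """Run one calibration/validation scheme over the whole model grid.

    Returns a report with one row per spec: pooled AIC (summed across the
    per-species fits), dAIC, Akaike weight and pooled validation R2 — the
    shape of a model-comparison table.
    """
    if env is not None and "ca_umol_mol" not in leaf_data.columns:
        leaf_data = attach_drivers(leaf_data, env)
    reports: list[dict] = []
    species_list = sorted(leaf_data["species"].unique())
    fits_by_species: dict[str, dict[str, FitResult]] = {}
    for sp in species_list:
        sub = leaf_data[leaf_data["species"] == sp].reset_index(drop=True)
        cal = sub.loc[_window_mask(sub, scheme.calibration_window, env)]
        if cal.empty:
            raise ValueError(f"scheme {scheme.name}: calibration window selected zero rows")
        fits_by_species[sp] = _fit_grid_one_species(cal, model_grid)

    for spec in model_grid:
        loglik = 0.0
        p = 0
        n = 0
        converged = True
        obs_all: list[np.ndarray] = []
        pred_all: list[np.ndarray] = []
        for sp in species_list:
            fit = fits_by_species[sp][spec.key]
            loglik += fit.loglik
            p += fit.p
            n += fit.n
            converged &= fit.converged
            sub = leaf_data[leaf_data["species"] == sp].reset_index(drop=True)
            val = sub.loc[_window_mask(sub, scheme.validation_window, env)]
            if val.empty:
                raise ValueError(f"scheme {scheme.name}: validation window selected zero rows")
            drivers = _drivers_from_frame(val)
            params = [fit.estimates[name] for name in spec.param_names]
            pred = predict_gs(spec, params, drivers, g1m=fit.g1m)
            obs_all.append(val["gs"].to_numpy(float))
            pred_all.append(np.asarray(pred, dtype=float))
        r2 = validation_r2(np.concatenate(obs_all), np.concatenate(pred_all))
        reports.append(
            {
                "model": spec.key,
                "family": spec.family,
                "g0": spec.include_g0,
                "oscillator": spec.include_oscillator,
                "scheme": scheme.name,
                "loglik": loglik,
                "p": p,
                "n": n,
                "aic": aic(loglik, p),
                "r2_validation": r2,
                "converged": converged,
            }
        )
    table = pd.DataFrame(reports)
    ok = table["converged"].to_numpy()
    if not ok.any():
        raise RuntimeError(f"scheme {scheme.name}: no converged fits")
    d = np.full(len(table), np.nan)
    w = np.full(len(table), np.nan)
    d[ok] = delta_aic(table.loc[ok, "aic"])
    w[ok] = akaike_weights(table.loc[ok, "aic"])
    table["delta_aic"] = d
    table["weight"] = w
    return table


def run_all_schemes(leaf_data: pd.DataFrame, env: pd.DataFrame | None = None, model_grid=MODEL_GRID) -> pd.DataFrame:
    """All three calibration/validation schemes, concatenated."""
    return pd.concat(
        [run_scheme(s, leaf_data, env, model_grid) for s in SCHEMES.values()], ignore_index=True
    )
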