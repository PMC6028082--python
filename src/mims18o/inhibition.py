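"""Sulfonamide inhibition: classical dose-response, tight binding, titration.

Two regimes matter here.  A classical competitive inhibitor at concentrations
far above the enzyme leaves fractional activity 1/(1 + I/Ki).  A tight-binding
inhibitor (Kd comparable to or below the enzyme concentration) depletes free
inhibitor, so the bound fraction follows the Morrison quadratic; titrating
activity to zero then reads out the active-enzyme concentration
stoichiometrically, which is how membrane CA content is quantified with
ethoxzolamide.  An impermeant inhibitor (N-3500) reaches only exofacial
pools, which is what isolates exofacial activity in whole cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "InhibitionSeries",
    "TightBindingFit",
    "UnidentifiableError",
    "fractional_activity",
    "estimate_enzyme_conc",
    "apply_impermeant_inhibitor",
]


class UnidentifiableError(ValueError):
    """Raised when the requested parameter cannot be resolved by the data."""


def fractional_activity(
    e_total: float, inhibitor: float, k: float, mode: str = "classical"
) -> float:
    """Fraction of enzyme activity remaining at inhibitor concentration I.

    classical: 1/(1 + I/Ki) (free inhibitor ~ total).
    tight: 1 - bound/E with bound = ((E+I+Kd) - sqrt((E+I+Kd)^2 - 4 E I))/2,
    the Morrison quadratic accounting for inhibitor depletion.
    ``inhibitor`` may be ``inf`` (saturating blockade -> 0).
    """
    if inhibitor < 0:
        raise ValueError("inhibitor concentration must be non-negative")
    if k <= 0:
        raise ValueError("inhibition constant must be positive")
    if e_total < 0:
        raise ValueError("enzyme concentration must be non-negative")
    if mode == "classical":
        if math.isinf(inhibitor):
            return 0.0
        return 1.0 / (1.0 + inhibitor / k)
    if mode == "tight":
        if e_total == 0:
            raise ValueError("tight-binding mode requires a positive enzyme total")
        if math.isinf(inhibitor):
            return 0.0
        s = e_total + inhibitor + k
        disc = s * s - 4.0 * e_total * inhibitor
        bound = (s - math.sqrt(max(disc, 0.0))) / 2.0
        return max(0.0, 1.0 - bound / e_total)
    raise ValueError(f"unknown inhibition mode {mode!r}")


@dataclass(frozen=True)
class InhibitionSeries:
    """One inhibitor titration: concentrations vs normalized activity."""

    inhibitor: str
    concentrations: tuple
    fractional_activities: tuple
    enzyme: str = ""
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        conc = tuple(float(c) for c in self.concentrations)
        act = tuple(float(a) for a in self.fractional_activities)
        object.__setattr__(self, "concentrations", conc)
        object.__setattr__(self, "fractional_activities", act)
        if len(conc) != len(act):
            raise ValueError("concentrations and activities differ in length")
        if len(conc) < 6:
            raise ValueError("an inhibition series needs at least 6 points")
        if any(c < 0 for c in conc):
            raise ValueError("concentrations must be non-negative")
        if list(conc) != sorted(conc):
            raise ValueError("concentrations must be sorted ascending")
        if conc[0] != 0.0:
            raise ValueError("series must include the zero-inhibitor point")
        tol = max(5.0 * self.noise_sd, 1e-9)
        if abs(act[0] - 1.0) > tol:
            raise ValueError("activity at zero inhibitor must be 1 within noise")


@dataclass(frozen=True)
class TightBindingFit:
    """Active-enzyme concentration and dissociation constant from titration."""

    e_total: float
    kd: float
    se_e_total: float
    se_kd: float
    n_points: int

    def __post_init__(self) -> None:
        if self.e_total <= 0 or self.kd <= 0:
            raise ValueError("e_total and kd must be positive")


def _tight_model(i: np.ndarray, e_total: float, kd: float) -> np.ndarray:
    s = e_total + i + kd
    disc = np.maximum(s * s - 4.0 * e_total * i, 0.0)
    bound = (s - np.sqrt(disc)) / 2.0
    return 1.0 - bound / e_total


def _initial_e_total(conc: np.ndarray, act: np.ndarray) -> float:
    """Extrapolate the steep titration region to zero activity.

    In the stoichiometric limit activity falls linearly with I and crosses
    zero at I = E; a line through the steep points gives the intercept.
    """
    steep = (act <= 0.85) & (act >= 0.15)
    if steep.sum() >= 2:
        slope, intercept = np.polyfit(conc[steep], act[steep], 1)
        if slope < 0:
            e0 = -intercept / slope
            if e0 > 0:
                return float(e0)
    # fall back to the concentration nearest half-maximal activity
    return float(conc[np.argmin(np.abs(act - 0.5))]) or float(conc[-1]) / 2.0


def estimate_enzyme_conc(
    series: InhibitionSeries, kd_known: Optional[float] = None
) -> TightBindingFit:
    """Fit the Morrison tight-binding form for total active enzyme.

    Fits E_total (and Kd unless ``kd_known`` is given) by nonlinear least
    squares.  Requires the series to actually span the titration (activity
    from above 0.9 down to below 0.2); raises
    :class:`UnidentifiableError` when the data are in the classical regime
    (E << Kd) where the response carries no information about E_total.
    """
    conc = np.asarray(series.concentrations, dtype=float)
    act = np.asarray(series.fractional_activities, dtype=float)
    if act.max() <= 0.9 or act.min() >= 0.2:
        raise ValueError(
            "series does not span the titration (need activity from >0.9 "
            "down to <0.2); extend the concentration range"
        )
    e0 = _initial_e_total(conc, act)
    tols = dict(xtol=1e-14, ftol=1e-14, gtol=1e-14, maxfev=50000)
    # fit in log space: both parameters are positive scale parameters and the
    # (E, Kd) surface is badly conditioned in linear coordinates
    if kd_known is not None:
        popt, pcov = curve_fit(
            lambda i, log_e: _tight_model(i, 10.0**log_e, kd_known),
            conc,
            act,
            p0=[np.log10(e0)],
            **tols,
        )
        e_fit, kd_fit = float(10.0 ** popt[0]), float(kd_known)
        j = e_fit * np.log(10.0)  # delta-method back-transform
        se_e = float(np.sqrt(pcov[0, 0])) * j if np.isfinite(pcov[0, 0]) else np.inf
        se_kd = 0.0
    else:
        popt, pcov = curve_fit(
            lambda i, log_e, log_kd: _tight_model(i, 10.0**log_e, 10.0**log_kd),
            conc,
            act,
            p0=[np.log10(e0), np.log10(max(e0 / 4.0, 1e-12))],
            **tols,
        )
        e_fit, kd_fit = float(10.0 ** popt[0]), float(10.0 ** popt[1])
        diag = np.diag(pcov)
        ln10 = np.log(10.0)
        se_e = float(np.sqrt(diag[0])) * e_fit * ln10 if np.isfinite(diag[0]) else np.inf
        se_kd = float(np.sqrt(diag[1])) * kd_fit * ln10 if np.isfinite(diag[1]) else np.inf
    # classical-regime data: the Morrison form degenerates to 1/(1+I/Kd) and
    # E_total is a flat direction of the likelihood
    if not np.isfinite(se_e) or se_e > 0.5 * e_fit or kd_fit > 50.0 * e_fit:
        raise UnidentifiableError(
            "E_total is not identifiable: the series is in the classical "
            "regime (E << Kd); use a tighter inhibitor or more enzyme"
        )
    return TightBindingFit(
        e_total=e_fit, kd=kd_fit, se_e_total=se_e, se_kd=se_kd, n_points=len(conc)
    )


def apply_impermeant_inhibitor(layout, inhibitor: str, concentration: float):
    """Scale enzyme pools for an inhibitor added to the extracellular medium.

    Exofacial pools are always reached; intracellular pools only when the
    inhibitor is flagged permeant for that pool.  Returns a new layout with
    pool concentrations scaled by the remaining fractional activity (the
    titration picture of inhibition).
    """
    if concentration < 0:
        raise ValueError("inhibitor concentration must be non-negative")
    new_pools = []
    for pool in layout.pools:
        if inhibitor not in pool.inhibitor_constants:
            raise KeyError(
                f"pool {pool.name!r} has no constant for inhibitor {inhibitor!r}"
            )
        spec = pool.inhibitor_constants[inhibitor]
        reaches = pool.compartment == "exofacial" or spec.permeant
        if reaches and concentration > 0:
            f = fractional_activity(
                pool.concentration, concentration, spec.constant, mode=spec.mode
            )
            pool = replace(pool, concentration=pool.concentration * f)
        new_pools.append(pool)
    return replace(layout, pools=tuple(new_pools))


def fit_classical_ki(series: InhibitionSeries) -> tuple:
    """Fit activity = 1/(1 + I/Ki); returns (ki, se_ki).

    The read-out for impermeant-inhibitor dose-response series where the
    enzyme is far below the inhibitor (no depletion).
    """
    conc = np.asarray(series.concentrations, dtype=float)
    act = np.asarray(series.fractional_activities, dtype=float)
    half = conc[np.argmin(np.abs(act - 0.5))]
    p0 = [half if half > 0 else np.median(conc[conc > 0])]
    popt, pcov = curve_fit(
        lambda i, ki: 1.0 / (1.0 + i / ki),
        conc,
        act,
        p0=p0,
        bounds=(1e-15, np.inf),
        maxfev=20000,
    )
    se = float(np.sqrt(pcov[0, 0])) if np.isfinite(pcov[0, 0]) else np.inf
    return float(popt[0]), se


__all__.append("fit_classical_ki")
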