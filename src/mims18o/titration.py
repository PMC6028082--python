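"""pH dependence of catalytic efficiency: fitting and equilibrium transforms.

Hydration-direction efficiency follows a single-ionization titration,
eff(pH) = A / (1 + 10**(pKa - pH)), with A the pH-independent maximum and pKa
the apparent ionization (conventionally the zinc-bound water).  At chemical
equilibrium one interconversion flux underlies both reaction directions, so
the dehydration-direction efficiency is not fitted separately: it follows
from the hydration fit by the equilibrium-flux (Haldane) relation
eff_dehyd(pH) = eff_hyd(pH) * 10**(pK1 - pH).  The same arithmetic predicts
how the exchange rate constant responds to an acute pH shift.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .carbonate import DEFAULT_PK1, AssayConditions, speciate
from .exchange import (
    EnzymePool,
    Layout,
    build_transfer_matrix,
    slow_eigenvalue,
)

__all__ = [
    "TitrationCurve",
    "TitrationFit",
    "fit_titration",
    "haldane_transform",
    "predict_fold_change",
    "BackgroundDominatedWarning",
]


class BackgroundDominatedWarning(UserWarning):
    """Catalyzed rate is not well separated from the uncatalyzed background."""


@dataclass(frozen=True)
class TitrationCurve:
    """Efficiency (or R1/E) measured across a pH grid, one direction."""

    ph_values: tuple
    efficiency: tuple
    direction: str = "hydration"
    enzyme: str = ""

    def __post_init__(self) -> None:
        ph = tuple(float(p) for p in self.ph_values)
        eff = tuple(float(e) for e in self.efficiency)
        object.__setattr__(self, "ph_values", ph)
        object.__setattr__(self, "efficiency", eff)
        if len(ph) != len(eff):
            raise ValueError("ph_values and efficiency differ in length")
        if len(set(ph)) < 5:
            raise ValueError("a titration needs >= 5 distinct pH points")
        if max(ph) - min(ph) < 1.5:
            raise ValueError("a titration must span >= 1.5 pH units")
        if self.direction not in ("hydration", "dehydration"):
            raise ValueError(f"unknown direction {self.direction!r}")


@dataclass(frozen=True)
class TitrationFit:
    """Single-ionization fit: maximal efficiency A and apparent pKa."""

    a_max: float
    pKa: float
    se_a: float
    se_pKa: float
    direction: str
    n_points: int
    enzyme: str = ""

    def __post_init__(self) -> None:
        if self.a_max <= 0:
            raise ValueError("a_max must be positive")

    def efficiency(self, ph) -> np.ndarray:
        ph = np.asarray(ph, dtype=float)
        return self.a_max / (1.0 + 10.0 ** (self.pKa - ph))


def _titration_model(ph: np.ndarray, a: float, pka: float) -> np.ndarray:
    return a / (1.0 + 10.0 ** (pka - ph))


def _initial_guess(ph: np.ndarray, eff: np.ndarray) -> tuple:
    a0 = eff.max() * 1.05
    half = a0 / 2.0
    order = np.argsort(ph)
    ph_s, eff_s = ph[order], eff[order]
    above = eff_s >= half
    if above.any() and not above.all():
        i = int(np.argmax(above))
        if i == 0:
            pka0 = ph_s[0]
        else:
            x0, x1 = ph_s[i - 1], ph_s[i]
            y0, y1 = eff_s[i - 1], eff_s[i]
            pka0 = x0 + (half - y0) * (x1 - x0) / (y1 - y0) if y1 != y0 else x0
    else:
        pka0 = float(np.median(ph_s))
    return float(a0), float(pka0)


def fit_titration(curve: TitrationCurve, max_restarts: int = 5) -> TitrationFit:
    """Nonlinear least squares of the single-ionization model.

    Initialized from the half-maximum crossing; on non-convergence the start
    is jittered deterministically a bounded number of times before giving up
    with diagnostics.  A flat curve (range < 10% of its maximum) is rejected
    as untitratable.
    """
    if curve.direction != "hydration":
        raise ValueError("fit_titration expects a hydration-direction curve")
    ph = np.asarray(curve.ph_values, dtype=float)
    eff = np.asarray(curve.efficiency, dtype=float)
    if eff.max() <= 0:
        raise ValueError("efficiencies must be positive")
    if (eff.max() - eff.min()) < 0.1 * eff.max():
        raise ValueError(
            "curve is flat (range < 10% of maximum); pKa is untitratable "
            "over this pH span"
        )
    a0, pka0 = _initial_guess(ph, eff)
    bounds = ([0.0, ph.min() - 1.0], [np.inf, ph.max() + 1.0])
    rng = np.random.default_rng(0)
    last_err: Optional[Exception] = None
    for attempt in range(max_restarts + 1):
        p0 = [a0, pka0]
        if attempt:
            p0 = [
                a0 * float(rng.uniform(0.5, 2.0)),
                float(np.clip(pka0 + rng.uniform(-1, 1), *[b[1] for b in bounds])),
            ]
            p0[1] = float(np.clip(p0[1], bounds[0][1], bounds[1][1]))
        try:
            popt, pcov = curve_fit(
                _titration_model,
                ph,
                eff,
                p0=p0,
                bounds=bounds,
                xtol=1e-12,
                ftol=1e-12,
                gtol=1e-12,
                maxfev=20000,
            )
            diag = np.diag(pcov)
            return TitrationFit(
                a_max=float(popt[0]),
                pKa=float(popt[1]),
                se_a=float(np.sqrt(diag[0])) if np.isfinite(diag[0]) else np.inf,
                se_pKa=float(np.sqrt(diag[1])) if np.isfinite(diag[1]) else np.inf,
                direction="hydration",
                n_points=len(ph),
                enzyme=curve.enzyme,
            )
        except RuntimeError as err:  # non-convergence
            last_err = err
    raise RuntimeError(
        f"titration fit failed after {max_restarts} restarts "
        f"(start A={a0:.3g}, pKa={pka0:.3g}): {last_err}"
    )


def haldane_transform(
    fit: TitrationFit, pk1_apparent: float = DEFAULT_PK1
) -> Callable[[np.ndarray], np.ndarray]:
    """Dehydration-direction efficiency implied by the hydration fit.

    At chemical equilibrium the hydration flux eff_hyd * [CO2] equals the
    dehydration flux eff_dehyd * [HCO3-]; with [HCO3-]/[CO2] = 10**(pH - pK1)
    this gives eff_dehyd(pH) = eff_hyd(pH) * 10**(pK1 - pH).
    """
    if fit.direction != "hydration":
        raise ValueError("haldane_transform expects a hydration-direction fit")

    def dehydration_efficiency(ph) -> np.ndarray:
        ph = np.asarray(ph, dtype=float)
        return fit.efficiency(ph) * 10.0 ** (pk1_apparent - ph)

    return dehydration_efficiency


def predict_fold_change(
    enzyme: EnzymePool,
    conditions: AssayConditions,
    ph_from: float,
    ph_to: float,
    pk1_apparent: float = DEFAULT_PK1,
    background_ratio_warn: float = 0.2,
) -> float:
    """Fold change of the background-subtracted exchange rate between two pH.

    Recomputes the CO2/HCO3- speciation at each pH, builds the
    single-compartment (ghost) model with the same enzyme concentration, and
    takes the ratio of slow eigenvalues after subtracting the enzyme-free
    background.  This is a genuine model prediction: the fold emerges from
    the speciation shift and the titration factor, not from any stored value.
    """
    layout = Layout(pools=(enzyme,), name=f"{enzyme.name}-ghost")
    folds = {}
    for ph in (ph_from, ph_to):
        cond = conditions.at_ph(ph)
        spec = speciate(cond, pk1_apparent=pk1_apparent)
        total = slow_eigenvalue(
            build_transfer_matrix(layout, cond, speciation=spec)
        )
        bg = slow_eigenvalue(
            build_transfer_matrix(
                layout.with_exofacial_concentration(0.0), cond, speciation=spec
            )
        )
        catalyzed = total - bg
        if catalyzed <= 0:
            raise ValueError(f"no catalyzed rate above background at pH {ph}")
        if catalyzed < background_ratio_warn * bg:
            warnings.warn(
                f"catalyzed rate at pH {ph} is within {background_ratio_warn:.0%} "
                "of the uncatalyzed background; the fold change is "
                "background-dominated",
                BackgroundDominatedWarning,
                stacklevel=2,
            )
        folds[ph] = catalyzed
    return folds[ph_to] / folds[ph_from]
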