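"""Recover first-order rate constants from progress curves.

The atom fraction of 18O in extracellular CO2 decays (asymptotically) as a
single exponential, so the operational fit is ordinary least squares of
ln(alpha) on time inside a phase window.  Whole-cell curves with intracellular
CAII are biphasic: an early window right after cell addition reports
intracellular activity, a late window reports exofacial activity.  The fitted
constant converts to the equilibrium interconversion flux R1 by inverting the
single-compartment (ghost) model, and to a catalytic efficiency by dividing
out enzyme and CO2 concentrations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import brentq, curve_fit
from scipy.stats import linregress

from .carbonate import AssayConditions, speciate
from .exchange import Layout, Trace, build_transfer_matrix, slow_eigenvalue

__all__ = [
    "PhaseWindows",
    "FirstOrderFit",
    "fit_first_order",
    "fit_exponential",
    "segment_phases",
    "efficiency_from_kobs",
    "EfficiencyResult",
]

DEFAULT_EARLY = (130.0, 180.0)
DEFAULT_LATE = (250.0, 450.0)


@dataclass(frozen=True)
class PhaseWindows:
    """Time windows (s) for the two phases of a biphasic progress curve."""

    early: tuple = DEFAULT_EARLY
    late: tuple = DEFAULT_LATE

    def __post_init__(self) -> None:
        for name, (start, end) in (("early", self.early), ("late", self.late)):
            if start >= end:
                raise ValueError(f"{name} window start must precede its end")
        if self.early[1] > self.late[0]:
            raise ValueError("early window must precede the late window")


@dataclass(frozen=True)
class FirstOrderFit:
    """Result of a log-linear regression on one window."""

    k_obs: float
    intercept: float
    window: tuple
    r_squared: float
    residual_sd: float
    n_points: int


def fit_first_order(trace: Trace, window: tuple) -> FirstOrderFit:
    """OLS of ln(alpha) on time within the window; k_obs = |slope|.

    Rejects windows containing non-positive alpha (the log is undefined) or
    fewer than 4 samples.
    """
    start, end = window
    mask = (trace.times >= start) & (trace.times <= end)
    t = trace.times[mask]
    a = trace.alpha[mask]
    if len(t) < 4:
        raise ValueError(f"window {window} holds {len(t)} points; need >= 4")
    if (a <= 0).any():
        raise ValueError(f"window {window} contains non-positive atom fractions")
    log_a = np.log(a)
    res = linregress(t, log_a)
    fitted = res.intercept + res.slope * t
    resid = log_a - fitted
    dof = max(len(t) - 2, 1)
    return FirstOrderFit(
        k_obs=abs(res.slope),
        intercept=float(res.intercept),
        window=(float(start), float(end)),
        r_squared=float(res.rvalue**2),
        residual_sd=float(np.sqrt((resid**2).sum() / dof)),
        n_points=int(len(t)),
    )


def fit_exponential(trace: Trace, window: tuple) -> FirstOrderFit:
    """Nonlinear single-exponential refit alpha = a0 * exp(-k t); cross-check.

    Offered as a sanity check on the log-linear route; weights are uniform on
    alpha rather than on ln(alpha).
    """
    start, end = window
    mask = (trace.times >= start) & (trace.times <= end)
    t = trace.times[mask]
    a = trace.alpha[mask]
    if len(t) < 4:
        raise ValueError(f"window {window} holds {len(t)} points; need >= 4")
    lin = fit_first_order(trace, window)
    popt, _ = curve_fit(
        lambda tt, a0, k: a0 * np.exp(-k * tt),
        t,
        a,
        p0=[np.exp(lin.intercept), lin.k_obs],
        maxfev=20000,
    )
    fitted = popt[0] * np.exp(-popt[1] * t)
    resid = a - fitted
    ss_tot = ((a - a.mean()) ** 2).sum()
    r2 = 1.0 - (resid**2).sum() / ss_tot if ss_tot > 0 else 1.0
    return FirstOrderFit(
        k_obs=abs(float(popt[1])),
        intercept=float(np.log(popt[0])),
        window=(float(start), float(end)),
        r_squared=float(r2),
        residual_sd=float(resid.std(ddof=2)) if len(t) > 2 else 0.0,
        n_points=int(len(t)),
    )


def segment_phases(
    trace: Trace,
    mode: str = "default",
    grid_step: float = 5.0,
    trim: float = 10.0,
) -> PhaseWindows:
    """Choose the early/late phase windows for a trace.

    Default mode returns the conventional windows (130-180 s and 250-450 s)
    after checking the trace spans them.  Auto mode fits a two-segment
    piecewise-linear model to ln(alpha) over the post-addition region,
    scanning breakpoints on a coarse grid and trimming ``trim`` seconds on
    each side of the best breakpoint.
    """
    if mode == "default":
        if trace.times[-1] < DEFAULT_LATE[1] or trace.times[0] > DEFAULT_EARLY[0]:
            raise ValueError(
                f"trace spans [{trace.times[0]}, {trace.times[-1]}] s but the "
                f"default windows need [{DEFAULT_EARLY[0]}, {DEFAULT_LATE[1]}] s"
            )
        return PhaseWindows()
    if mode != "auto":
        raise ValueError(f"unknown segmentation mode {mode!r}")

    t_start = float(trace.metadata.get("t_add", trace.times[0]))
    mask = (trace.times >= t_start) & (trace.alpha > 0)
    t = trace.times[mask]
    log_a = np.log(trace.alpha[mask])
    if len(t) < 8:
        raise ValueError("too few positive samples after the start for auto mode")

    def sse(tt: np.ndarray, yy: np.ndarray) -> float:
        if len(tt) < 2:
            return np.inf
        coeffs = np.polyfit(tt, yy, 1)
        r = yy - np.polyval(coeffs, tt)
        return float((r**2).sum())

    candidates = np.arange(t[0] + 4 * grid_step, t[-1] - 4 * grid_step, grid_step)
    if len(candidates) == 0:
        raise ValueError("trace too short to scan for a breakpoint")
    best_bp, best_sse = None, np.inf
    for bp in candidates:
        left = t <= bp
        total = sse(t[left], log_a[left]) + sse(t[~left], log_a[~left])
        if total < best_sse:
            best_sse, best_bp = total, bp
    early = (float(t[0]), float(best_bp - trim))
    late = (float(best_bp + trim), float(t[-1]))
    return PhaseWindows(early=early, late=late)


@dataclass(frozen=True)
class EfficiencyResult:
    """Enzyme-normalized outputs derived from a fitted rate constant."""

    r1: float
    r1_over_e: float
    efficiency: float
    k_obs: float
    background_eigenvalue: float
    enzyme_concentration: float
    co2: float
    metadata: dict = field(default_factory=dict)


def efficiency_from_kobs(
    fit: FirstOrderFit,
    conditions: AssayConditions,
    layout: Layout,
    enzyme_concentration: Optional[float] = None,
    pk1_apparent: Optional[float] = None,
) -> EfficiencyResult:
    """Convert a fitted k_obs into R1/E and kcat_exch/K_eff_CO2.

    Numerically inverts the single-compartment (ghost) model: finds the
    catalyzed flux R1 whose slow eigenvalue, on top of the uncatalyzed
    background, reproduces ``fit.k_obs``.  The efficiency divides R1/E by
    [CO2], valid in the sub-saturation regime the assay operates in.
    Background subtraction happens in rate (flux) space, where contributions
    are exactly additive, not on the fitted slopes.
    """
    exo = layout.exofacial_pools()
    if enzyme_concentration is None:
        if not exo:
            raise ValueError("no exofacial pool and no enzyme concentration given")
        enzyme_concentration = sum(p.concentration for p in exo)
    if enzyme_concentration <= 0:
        raise ValueError("enzyme concentration must be positive")
    spec_kwargs = {} if pk1_apparent is None else {"pk1_apparent": pk1_apparent}
    speciation = speciate(conditions, **spec_kwargs)

    if not exo:
        raise ValueError("efficiency inversion needs an exofacial pool template")
    template = exo[0]
    ghost = Layout(pools=(template,), name="ghost-inversion")

    def eig_for_r1(r1: float) -> float:
        # express the flux as a concentration of the template pool
        per_e = (
            template.efficiency_max
            * speciation.co2
            / (1.0 + 10.0 ** (template.pKa_apparent - conditions.ph))
        )
        lay = ghost.with_exofacial_concentration(r1 / per_e if per_e > 0 else 0.0)
        return slow_eigenvalue(
            build_transfer_matrix(lay, conditions, speciation=speciation)
        )

    background = eig_for_r1(0.0)
    if fit.k_obs < background * (1.0 - 1e-9):
        raise ValueError(
            f"k_obs {fit.k_obs:.4e} 1/s is below the uncatalyzed background "
            f"eigenvalue {background:.4e} 1/s"
        )
    if fit.k_obs <= background:
        r1 = 0.0
    else:
        hi = speciation.co2 * fit.k_obs * 10.0
        while eig_for_r1(hi) < fit.k_obs:
            hi *= 4.0
        r1 = brentq(lambda r: eig_for_r1(r) - fit.k_obs, 0.0, hi, rtol=1e-12)
    r1_over_e = r1 / enzyme_concentration
    return EfficiencyResult(
        r1=r1,
        r1_over_e=r1_over_e,
        efficiency=r1_over_e / speciation.co2,
        k_obs=fit.k_obs,
        background_eigenvalue=background,
        enzyme_concentration=enzyme_concentration,
        co2=speciation.co2,
        metadata={"window": fit.window},
    )
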