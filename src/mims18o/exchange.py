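"""Forward simulator of 18O loss from the CO2/HCO3- pool at chemical equilibrium.

The chemistry sits at equilibrium, so nothing happens to the chemical
concentrations; what evolves is the isotope label.  Every hydration event
converts a CO2 molecule into a bicarbonate while adding one oxygen drawn from
the (effectively infinite, unlabeled) water pool; every dehydration event
converts a bicarbonate back into CO2 while discarding one of its three oxygens
into water, uniformly at random.  Repeated cycling therefore washes 18O out of
the carbon pool, and the washout rate reports the interconversion flux -- i.e.
carbonic anhydrase activity -- without any net chemistry.

The state is isotopologue-resolved: per compartment, CO2 with 0..2 labeled
oxygens (3 states) and HCO3- with 0..3 (4 states), plus a single absorbing
counter for 18O released to water (in moles, so it is conserved across
compartments of different volume).  The dynamics are linear and
time-invariant between events, so the progress curve has a closed matrix-
exponential solution; a step-wise numerical integration is kept as an
independent route for cross-checking.

Intact cells are a second compartment: CO2 isotopologues exchange across the
membrane with a first-order constant, bicarbonate is impermeant, and
intracellular carbonic anhydrase (CAII) strips label from CO2 that visits the
cell.  Membrane ghosts expose their (exofacial) enzyme directly in the single
extracellular compartment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import expm
from scipy.optimize import brentq
from scipy.special import comb

from .carbonate import (
    DEFAULT_KH_16C,
    DEFAULT_Q10,
    AssayConditions,
    CarbonateSpeciation,
    speciate,
    uncatalyzed_rates,
)
from .inhibition import fractional_activity

__all__ = [
    "InhibitorSpec",
    "EnzymePool",
    "Layout",
    "IsotopologueState",
    "TransferMatrix",
    "Trace",
    "Event",
    "NonEquilibriumError",
    "titration_factor",
    "catalyzed_flux",
    "initial_isotope_state",
    "build_transfer_matrix",
    "simulate_trace",
    "run_assay",
    "slow_eigenvalue",
    "atom_exchange_eigenvalue",
    "calibrate_activity_to_kobs",
]

EXOFACIAL = "exofacial"
INTRACELLULAR = "intracellular"

#: Default first-order CO2 exchange constant between medium and cells,
#: expressed on the extracellular concentration (1/s).  Shapes only the early
#: phase of whole-cell curves; the intracellular-side constant follows from
#: volume balance.  Chosen fast enough that the post-addition transient is
#: fully decayed before the late fitting window opens.
DEFAULT_CO2_EXCHANGE_RATE = 0.15

#: Default single-cell volume, pL.
DEFAULT_CELL_VOLUME_PL = 2.0


class NonEquilibriumError(ValueError):
    """Raised when a speciation is not at chemical equilibrium for the run."""


@dataclass(frozen=True)
class InhibitorSpec:
    """How one inhibitor acts on one enzyme pool.

    ``constant`` is Ki (classical mode, simple competitive dose-response) or
    Kd (tight mode, Morrison quadratic); ``permeant`` controls whether the
    inhibitor reaches intracellular pools.
    """

    constant: float
    mode: str = "classical"
    permeant: bool = False

    def __post_init__(self) -> None:
        if self.constant <= 0:
            raise ValueError("inhibition constant must be positive")
        if self.mode not in ("classical", "tight"):
            raise ValueError(f"unknown inhibition mode {self.mode!r}")


@dataclass(frozen=True)
class EnzymePool:
    """One carbonic anhydrase isoform in one compartment.

    ``efficiency_max`` is A, the pH-independent maximum of the hydration-
    direction catalytic efficiency kcat_exch/K_eff_CO2 (M^-1 s^-1);
    ``pKa_apparent`` is the single ionization governing its pH dependence.
    ``K_eff_co2 = None`` means the enzyme stays strictly first-order in CO2
    (sub-saturation), which is the regime the exchange assay reports.
    """

    name: str
    compartment: str
    concentration: float
    efficiency_max: float
    pKa_apparent: float
    K_eff_co2: Optional[float] = None
    inhibitor_constants: Mapping[str, InhibitorSpec] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.compartment not in (EXOFACIAL, INTRACELLULAR):
            raise ValueError(f"unknown compartment {self.compartment!r}")
        if self.concentration < 0:
            raise ValueError("concentration must be non-negative")
        if self.efficiency_max <= 0:
            raise ValueError("efficiency_max must be positive")
        if not (4.0 <= self.pKa_apparent <= 9.0):
            raise ValueError("pKa_apparent must lie in [4, 9]")


@dataclass(frozen=True)
class Layout:
    """Enzyme pools plus the compartment geometry they live in.

    A layout with any intracellular pool is a two-compartment (whole-cell)
    model; otherwise a single extracellular compartment (ghosts, CAII-free
    cells).  ``co2_exchange_rate`` acts on the extracellular CO2
    concentration; the intracellular-side constant is scaled by the volume
    ratio so total CO2 is conserved.
    """

    pools: tuple
    co2_exchange_rate: float = DEFAULT_CO2_EXCHANGE_RATE
    cell_volume_pl: float = DEFAULT_CELL_VOLUME_PL
    name: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "pools", tuple(self.pools))

    @property
    def compartments(self) -> tuple:
        if any(p.compartment == INTRACELLULAR for p in self.pools):
            return (EXOFACIAL, INTRACELLULAR)
        return (EXOFACIAL,)

    @property
    def n_compartments(self) -> int:
        return len(self.compartments)

    def exofacial_pools(self) -> tuple:
        return tuple(p for p in self.pools if p.compartment == EXOFACIAL)

    def scale_exofacial(self, factor: float) -> "Layout":
        """Return a copy with all exofacial pool concentrations scaled."""
        pools = tuple(
            replace(p, concentration=p.concentration * factor)
            if p.compartment == EXOFACIAL
            else p
            for p in self.pools
        )
        return replace(self, pools=pools)

    def with_exofacial_concentration(self, concentration: float) -> "Layout":
        pools = tuple(
            replace(p, concentration=concentration)
            if p.compartment == EXOFACIAL
            else p
            for p in self.pools
        )
        return replace(self, pools=pools)


# state vector layout per compartment: [co2_0, co2_1, co2_2, hco3_0..hco3_3]
_STATES_PER_COMPARTMENT = 7
_CO2_SLOTS = slice(0, 3)
_HCO3_SLOTS = slice(3, 7)


@dataclass
class IsotopologueState:
    """Isotopologue concentrations per compartment plus the water sink.

    ``co2`` has shape (n_compartments, 3) -- CO2 with 0, 1, 2 18O atoms;
    ``hco3`` has shape (n_compartments, 4).  Concentrations are mol/L in each
    compartment's own volume; ``released_18o`` is cumulative 18O handed to
    water, in mol (absolute), so that the global label budget closes.
    """

    co2: np.ndarray
    hco3: np.ndarray
    released_18o: float = 0.0

    def __post_init__(self) -> None:
        self.co2 = np.atleast_2d(np.asarray(self.co2, dtype=float))
        self.hco3 = np.atleast_2d(np.asarray(self.hco3, dtype=float))
        if self.co2.shape[1] != 3 or self.hco3.shape[1] != 4:
            raise ValueError("co2 needs 3 isotopologues, hco3 needs 4")
        if self.co2.shape[0] != self.hco3.shape[0]:
            raise ValueError("co2 and hco3 compartment counts differ")
        if (self.co2 < -1e-15).any() or (self.hco3 < -1e-15).any():
            raise ValueError("negative isotopologue concentration")

    @property
    def n_compartments(self) -> int:
        return self.co2.shape[0]

    def alpha(self, compartment: int = 0) -> float:
        """18O atom fraction in the CO2 of one compartment."""
        c = self.co2[compartment]
        total_o = 2.0 * c.sum()
        if total_o == 0:
            return 0.0
        return (c[1] + 2.0 * c[2]) / total_o

    def labeled_atoms(self, volumes: Sequence[float]) -> float:
        """Total 18O in all chemical species, mol (excludes the sink)."""
        weights_c = np.array([0.0, 1.0, 2.0])
        weights_b = np.array([0.0, 1.0, 2.0, 3.0])
        per_comp = self.co2 @ weights_c + self.hco3 @ weights_b
        return float(per_comp @ np.asarray(volumes, dtype=float))

    def to_vector(self) -> np.ndarray:
        n = self.n_compartments
        v = np.empty(n * _STATES_PER_COMPARTMENT + 1)
        for k in range(n):
            base = k * _STATES_PER_COMPARTMENT
            v[base : base + 3] = self.co2[k]
            v[base + 3 : base + 7] = self.hco3[k]
        v[-1] = self.released_18o
        return v

    @classmethod
    def from_vector(cls, v: np.ndarray, n_compartments: int) -> "IsotopologueState":
        co2 = np.empty((n_compartments, 3))
        hco3 = np.empty((n_compartments, 4))
        for k in range(n_compartments):
            base = k * _STATES_PER_COMPARTMENT
            co2[k] = v[base : base + 3]
            hco3[k] = v[base + 3 : base + 7]
        return cls(co2=np.clip(co2, 0.0, None), hco3=np.clip(hco3, 0.0, None),
                   released_18o=float(v[-1]))


@dataclass(frozen=True)
class TransferMatrix:
    """Linear generator of the isotopologue dynamics plus its geometry."""

    matrix: np.ndarray
    volumes: tuple
    layout: Layout
    speciation: CarbonateSpeciation
    conditions: AssayConditions

    @property
    def n_compartments(self) -> int:
        return len(self.volumes)


@dataclass
class Trace:
    """(time, 18O atom fraction of extracellular CO2) series.

    This is the quantity the membrane-inlet mass spectrometer reports; its
    decline is the progress curve every fit operates on.
    """

    times: np.ndarray
    alpha: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.alpha = np.asarray(self.alpha, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.alpha.shape:
            raise ValueError("times and alpha must be 1-D and equal length")
        if len(self.times) < 8:
            raise ValueError("a trace needs at least 8 samples")
        if not (np.diff(self.times) > 0).all():
            raise ValueError("times must be strictly increasing")
        if (self.alpha < -1e-12).any() or (self.alpha > 1.0 + 1e-12).any():
            raise ValueError("alpha must lie in [0, 1]")

    @property
    def span(self) -> float:
        return float(self.times[-1] - self.times[0])


@dataclass(frozen=True)
class Event:
    """A mid-run change of the system: new generator + state transform.

    ``transform`` maps the state just before the event to the state just
    after (e.g. splicing in a freshly added, unlabeled cell compartment).
    """

    time: float
    matrix: TransferMatrix
    transform: Callable[[IsotopologueState], IsotopologueState]


def titration_factor(pKa_apparent: float, ph: float) -> float:
    """Fraction of maximal efficiency at the given pH (single ionization)."""
    return 1.0 / (1.0 + 10.0 ** (pKa_apparent - ph))


def catalyzed_flux(
    pool: EnzymePool,
    speciation: CarbonateSpeciation,
    ph: float,
    inhibitors: Optional[Mapping[str, float]] = None,
) -> float:
    """Interconversion flux R1 contributed by one enzyme pool, mol/L/s.

    At chemical equilibrium R1 is simultaneously the hydration and the
    dehydration flux.  In the default sub-saturation regime
    R1 = f_active * E * A * [CO2] / (1 + 10**(pKa - pH)); with a finite
    K_eff_CO2 the saturating Michaelis form is used with kcat = A * K_eff.
    Inhibitors reach the pool if it is exofacial or if they are permeant.
    """
    f_active = 1.0
    if inhibitors:
        for name, conc in inhibitors.items():
            if conc < 0:
                raise ValueError(f"negative concentration for inhibitor {name!r}")
            if name not in pool.inhibitor_constants:
                raise KeyError(
                    f"pool {pool.name!r} has no constant for inhibitor {name!r}"
                )
            spec = pool.inhibitor_constants[name]
            if pool.compartment == INTRACELLULAR and not spec.permeant:
                continue
            f_active *= fractional_activity(
                pool.concentration, conc, spec.constant, mode=spec.mode
            )
    eff = pool.efficiency_max * titration_factor(pool.pKa_apparent, ph)
    co2 = speciation.co2
    if pool.K_eff_co2 is None:
        rate_per_e = eff * co2
    else:
        kcat = pool.efficiency_max * pool.K_eff_co2
        rate_per_e = (
            kcat * titration_factor(pool.pKa_apparent, ph) * co2
            / (pool.K_eff_co2 + co2)
        )
    return f_active * pool.concentration * rate_per_e


def initial_isotope_state(
    speciation: CarbonateSpeciation,
    enrichment: float,
    n_compartments: int = 1,
    labeled_compartment: int = 0,
) -> IsotopologueState:
    """Distribute the 18O label binomially over oxygen sites.

    Each oxygen site is labeled independently with probability ``enrichment``
    (2 sites per CO2, 3 per HCO3-), which is the equilibrium scrambling the
    instrument sees after the enriched species dissolve.  Compartments other
    than ``labeled_compartment`` start unlabeled at the same chemical
    concentrations.
    """
    if not (0.0 <= enrichment <= 1.0):
        raise ValueError("enrichment must lie in [0, 1]")
    co2 = np.zeros((n_compartments, 3))
    hco3 = np.zeros((n_compartments, 4))
    co2[:, 0] = speciation.co2
    hco3[:, 0] = speciation.hco3
    p = enrichment
    k = labeled_compartment
    co2[k] = speciation.co2 * np.array(
        [comb(2, j) * p**j * (1 - p) ** (2 - j) for j in range(3)]
    )
    hco3[k] = speciation.hco3 * np.array(
        [comb(3, j) * p**j * (1 - p) ** (3 - j) for j in range(4)]
    )
    return IsotopologueState(co2=co2, hco3=hco3, released_18o=0.0)


def _check_equilibrium(
    speciation: CarbonateSpeciation, conditions: AssayConditions
) -> None:
    total = speciation.co2 + speciation.hco3
    if not math.isclose(total, conditions.total_carbon, rel_tol=1e-9):
        raise NonEquilibriumError(
            f"speciation total {total:.6e} M does not match conditions "
            f"total_carbon {conditions.total_carbon:.6e} M"
        )
    if speciation.co2 <= 0 or speciation.hco3 <= 0:
        raise NonEquilibriumError("both CO2 and HCO3- must be present")
    log_ratio = math.log10(speciation.hco3 / speciation.co2)
    expected = conditions.ph - speciation.pk1_apparent
    if abs(log_ratio - expected) > 1e-9:
        raise NonEquilibriumError(
            f"speciation ratio log10(hco3/co2) = {log_ratio:.6f} is not the "
            f"equilibrium value pH - pK1 = {expected:.6f}"
        )


def _compartment_volumes(layout: Layout, conditions: AssayConditions) -> tuple:
    ve = conditions.vessel_volume
    if layout.n_compartments == 1:
        return (ve,)
    density = conditions.cell_density or 0.0
    vi = density * (ve * 1e3) * layout.cell_volume_pl * 1e-12
    if vi <= 0:
        raise ValueError(
            "two-compartment layout requires positive cell density and volume"
        )
    return (ve, vi)


def build_transfer_matrix(
    layout: Layout,
    conditions: AssayConditions,
    speciation: Optional[CarbonateSpeciation] = None,
    inhibitors: Optional[Mapping[str, float]] = None,
    include_enzymes: bool = True,
    k_h_16c: float = DEFAULT_KH_16C,
    q10: float = DEFAULT_Q10,
) -> TransferMatrix:
    """Assemble the linear generator of the isotopologue dynamics.

    Per compartment, the total interconversion flux F (catalyzed + uncatalyzed,
    mol/L/s) sets per-molecule rates kc = F/[CO2] for hydration and
    kb = F/[HCO3-] for dehydration; hydration preserves a molecule's labeled
    oxygens and adds an unlabeled one, dehydration discards one oxygen
    uniformly at random (probability j/3 that a j-labeled bicarbonate loses a
    label to the water sink).  CO2 isotopologues exchange between compartments;
    bicarbonate does not cross the membrane.
    """
    compartments = layout.compartments
    for pool in layout.pools:
        if pool.compartment not in compartments:
            raise ValueError(
                f"pool {pool.name!r} declared in compartment "
                f"{pool.compartment!r} absent from the layout"
            )
    if speciation is None:
        speciation = speciate(conditions)
    _check_equilibrium(speciation, conditions)
    volumes = _compartment_volumes(layout, conditions)
    ncomp = len(volumes)
    n = ncomp * _STATES_PER_COMPARTMENT + 1
    m = np.zeros((n, n))
    sink = n - 1

    background = uncatalyzed_rates(
        speciation, conditions.temperature_c, k_h_16c=k_h_16c, q10=q10
    )
    for k, comp_name in enumerate(compartments):
        flux = background.k_h * speciation.co2
        if include_enzymes:
            for pool in layout.pools:
                if pool.compartment == comp_name:
                    flux += catalyzed_flux(pool, speciation, conditions.ph, inhibitors)
        kc = flux / speciation.co2
        kb = flux / speciation.hco3
        base = k * _STATES_PER_COMPARTMENT
        c_idx = [base + j for j in range(3)]
        b_idx = [base + 3 + j for j in range(4)]
        # hydration: CO2(j) -> HCO3(j), gains an unlabeled water oxygen
        for j in range(3):
            m[c_idx[j], c_idx[j]] -= kc
            m[b_idx[j], c_idx[j]] += kc
        # dehydration: HCO3(j) -> CO2(j or j-1); one oxygen leaves to water
        for j in range(4):
            m[b_idx[j], b_idx[j]] -= kb
            p_lose_label = j / 3.0
            if j >= 1:
                m[c_idx[j - 1], b_idx[j]] += kb * p_lose_label
            if j <= 2:
                m[c_idx[j], b_idx[j]] += kb * (1.0 - p_lose_label)
            if j >= 1:
                m[sink, b_idx[j]] += volumes[k] * kb * p_lose_label

    if ncomp == 2:
        ke = layout.co2_exchange_rate
        ki = ke * volumes[0] / volumes[1]
        for j in range(3):
            e = j
            i = _STATES_PER_COMPARTMENT + j
            m[e, e] -= ke
            m[e, i] += ke
            m[i, e] += ki
            m[i, i] -= ki
    return TransferMatrix(
        matrix=m,
        volumes=volumes,
        layout=layout,
        speciation=speciation,
        conditions=conditions,
    )


def _alpha_from_vector(v: np.ndarray) -> float:
    c = v[0:3]
    total_o = 2.0 * c.sum()
    if total_o <= 0:
        return 0.0
    return float((c[1] + 2.0 * c[2]) / total_o)


def _propagate_expm(
    m: np.ndarray, y0: np.ndarray, rel_times: np.ndarray
) -> np.ndarray:
    """Closed-form solution y(t) = expm(M t) y0 at each relative time."""
    out = np.empty((len(rel_times), len(y0)))
    cache: dict = {}
    prev_t = 0.0
    y = y0.copy()
    for i, t in enumerate(rel_times):
        dt = t - prev_t
        if dt > 0:
            key = round(dt, 12)
            if key not in cache:
                cache[key] = expm(m * dt)
            y = cache[key] @ y
            prev_t = t
        out[i] = y
    return out


def _propagate_ivp(m: np.ndarray, y0: np.ndarray, rel_times: np.ndarray) -> np.ndarray:
    t_end = float(rel_times[-1]) if len(rel_times) else 0.0
    if t_end == 0.0:
        return np.tile(y0, (len(rel_times), 1))
    sol = solve_ivp(
        lambda _t, y: m @ y,
        (0.0, t_end),
        y0,
        method="LSODA",
        t_eval=rel_times,
        rtol=1e-11,
        atol=1e-14,
        jac=lambda _t, _y: m,
    )
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    return sol.y.T


def simulate_trace(
    state0: IsotopologueState,
    matrix: TransferMatrix,
    times: Sequence[float],
    events: Sequence[Event] = (),
    method: str = "expm",
    metadata: Optional[dict] = None,
) -> Trace:
    """Deterministically integrate the isotopologue system and read out alpha.

    ``method`` selects the solver route: "expm" (matrix exponential, the
    default) or "ivp" (step-wise stiff integration); the two agree to solver
    tolerance and serve as mutual oracles.  Events switch the generator and
    transform the state at their scheduled time (e.g. cell addition), and must
    fall inside the simulated span.
    """
    times = np.asarray(times, dtype=float)
    if not (np.diff(times) > 0).all():
        raise ValueError("times must be strictly increasing")
    if method not in ("expm", "ivp"):
        raise ValueError(f"unknown method {method!r}")
    events = sorted(events, key=lambda e: e.time)
    for ev in events:
        if not (times[0] <= ev.time <= times[-1]):
            raise ValueError(f"event at t={ev.time} outside simulated span")
    propagate = _propagate_expm if method == "expm" else _propagate_ivp

    alphas = np.empty(len(times))
    state = state0
    current = matrix
    t_start = float(times[0])
    remaining = list(events) + [None]
    idx = 0
    for ev in remaining:
        t_stop = float(times[-1]) if ev is None else ev.time
        sel = slice(idx, int(np.searchsorted(times, t_stop, side="right")))
        seg_times = times[sel]
        if len(seg_times):
            rel = seg_times - t_start
            ys = propagate(current.matrix, state.to_vector(), rel)
            for j, y in enumerate(ys):
                alphas[sel.start + j] = _alpha_from_vector(y)
            last = ys[-1]
            state = IsotopologueState.from_vector(last, current.n_compartments)
            # advance the reference state to the segment end even if the last
            # sample precedes it
            if seg_times[-1] < t_stop:
                y_end = propagate(
                    current.matrix, state.to_vector(), np.array([t_stop - seg_times[-1]])
                )[-1]
                state = IsotopologueState.from_vector(y_end, current.n_compartments)
        elif ev is not None and t_stop > t_start:
            y_end = propagate(
                current.matrix, state.to_vector(), np.array([t_stop - t_start])
            )[-1]
            state = IsotopologueState.from_vector(y_end, current.n_compartments)
        idx = sel.stop
        if ev is not None:
            state = ev.transform(state)
            current = ev.matrix
            t_start = ev.time

    meta = dict(metadata or {})
    meta.setdefault("event_times", [ev.time for ev in events])
    meta.setdefault("method", method)
    return Trace(times=times, alpha=np.clip(alphas, 0.0, 1.0), metadata=meta)


def _splice_unlabeled_compartment(
    speciation: CarbonateSpeciation,
) -> Callable[[IsotopologueState], IsotopologueState]:
    def transform(state: IsotopologueState) -> IsotopologueState:
        co2 = np.vstack([state.co2, np.array([[speciation.co2, 0.0, 0.0]])])
        hco3 = np.vstack([state.hco3, np.array([[speciation.hco3, 0.0, 0.0, 0.0]])])
        return IsotopologueState(co2=co2, hco3=hco3, released_18o=state.released_18o)

    return transform


def run_assay(
    layout: Layout,
    conditions: AssayConditions,
    times: Optional[Sequence[float]] = None,
    t_add: float = 120.0,
    inhibitors: Optional[Mapping[str, float]] = None,
    method: str = "expm",
    pk1_apparent: Optional[float] = None,
    metadata: Optional[dict] = None,
) -> Trace:
    """Simulate a full assay: labeled buffer first, enzyme added at ``t_add``.

    Before the addition only the uncatalyzed background runs in a single
    compartment; at ``t_add`` the layout's enzymes switch on, and a whole-cell
    layout splices in an unlabeled intracellular compartment.  ``times``
    defaults to 0..500 s sampled at 1 Hz.
    """
    if times is None:
        times = np.arange(0.0, 501.0, 1.0)
    spec_kwargs = {} if pk1_apparent is None else {"pk1_apparent": pk1_apparent}
    speciation = speciate(conditions, **spec_kwargs)
    bare = Layout(pools=(), name="background")
    pre = build_transfer_matrix(bare, conditions, speciation=speciation)
    post = build_transfer_matrix(
        layout, conditions, speciation=speciation, inhibitors=inhibitors
    )
    if layout.n_compartments == 2:
        transform = _splice_unlabeled_compartment(speciation)
    else:
        transform = lambda s: s  # noqa: E731 - same compartment, enzymes switch on
    state0 = initial_isotope_state(speciation, conditions.label_enrichment)
    meta = dict(metadata or {})
    meta.update({"t_add": t_add, "layout": layout.name, "ph": conditions.ph})
    return simulate_trace(
        state0,
        pre,
        times,
        events=[Event(time=t_add, matrix=post, transform=transform)],
        method=method,
        metadata=meta,
    )


def slow_eigenvalue(matrix: TransferMatrix) -> float:
    """Magnitude of the slowest nonzero decay mode of the generator.

    This is the first-order constant governing the late-time decline of the
    atom fraction, and the analytic oracle for what a log-linear regression on
    a late window recovers.
    """
    m = matrix.matrix
    scale = np.abs(m).max()
    if scale == 0.0:
        return 0.0
    eigvals = np.linalg.eigvals(m)
    rates = -eigvals.real
    tol = 1e-10 * scale
    nonzero = rates[rates > tol]
    if len(nonzero) == 0:
        return 0.0
    return float(nonzero.min())


def atom_exchange_eigenvalue(kc: float, kb: float) -> float:
    """Closed-form slow decay rate of labeled atoms in one compartment.

    Tracking labeled-oxygen concentrations x (in CO2) and y (in HCO3-):
    dx/dt = -kc x + (2/3) kb y, dy/dt = kc x - kb y, whose slow root is
    ((kc+kb) - sqrt((kc+kb)^2 - (4/3) kc kb)) / 2.  Used as an independent
    oracle for :func:`slow_eigenvalue`.
    """
    tr = kc + kb
    disc = tr * tr - (4.0 / 3.0) * kc * kb
    return (tr - math.sqrt(max(disc, 0.0))) / 2.0


def calibrate_activity_to_kobs(
    k_target: float,
    layout: Layout,
    conditions: AssayConditions,
    inhibitors: Optional[Mapping[str, float]] = None,
    rel_tol: float = 1e-8,
) -> Layout:
    """Scale the exofacial pool concentration so the slow eigenvalue hits k_target.

    Lets a layout be expressed directly in terms of a printed first-order rate
    constant.  Monotone in the concentration, so a bracketed root solve is
    exact to tolerance.  Rejects targets at or below the enzyme-free
    background, reporting the background value.
    """
    if not layout.exofacial_pools():
        raise ValueError("layout has no exofacial pool to calibrate")
    ref = layout.with_exofacial_concentration(1e-9)  # 1 nM reference scale

    def eig_at(scale: float) -> float:
        lay = ref.scale_exofacial(scale)
        tm = build_transfer_matrix(lay, conditions, inhibitors=inhibitors)
        return slow_eigenvalue(tm)

    background = eig_at(0.0)
    if k_target <= background * (1.0 + 1e-9):
        if k_target >= background * (1.0 - 1e-9):
            return ref.scale_exofacial(0.0)
        raise ValueError(
            f"k_target {k_target:.4e} 1/s is below the uncatalyzed "
            f"background eigenvalue {background:.4e} 1/s"
        )
    hi = 1.0
    while eig_at(hi) < k_target:
        hi *= 4.0
        if hi > 1e12:
            raise RuntimeError("calibration bracket expansion failed")
    scale = brentq(
        lambda s: eig_at(s) - k_target, 0.0, hi, xtol=1e-16, rtol=min(rel_tol, 1e-8)
    )
    return ref.scale_exofacial(scale)
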