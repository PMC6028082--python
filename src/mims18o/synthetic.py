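"""Synthetic instrument data: traces, titrations and inhibition series.

The raw mass-spectrometer traces behind the published kinetic constants were
never deposited, so this module generates them: every generator is a pure,
seeded function whose defaults encode the published study conditions (16 degC,
25 mM total labeled CO2 species, 2 mL vessel, 5e5 cells/mL, cell addition at
120 s) and whose kinetic parameters come from a frozen fixture registry of the
published values.  Noise is multiplicative log-normal -- instrument noise
scales with signal -- with default relative sd 0.5% on atom fractions and 5%
on efficiencies.

Whole-cell entries are expressed as the late-phase first-order rate constant
they must produce; the generator calibrates the exofacial enzyme concentration
by eigenvalue inversion so the simulated curve reproduces that constant.
UFH-001 carries intracellular CAII and yields biphasic curves; the CAII-free
lines (HBL-100, T47D, MCF7) and membrane ghosts are single-compartment and
decay log-linearly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Mapping, Optional, Sequence

import numpy as np

from .carbonate import AssayConditions, speciate
from .exchange import (
    EnzymePool,
    InhibitorSpec,
    Layout,
    Trace,
    calibrate_activity_to_kobs,
    catalyzed_flux,
    run_assay,
)
from .inhibition import InhibitionSeries, fractional_activity
from .titration import TitrationCurve

__all__ = [
    "CellLineEntry",
    "MembraneEntry",
    "InhibitorEntry",
    "FixtureSet",
    "fixtures",
    "standard_conditions",
    "build_layout",
    "generate_trace",
    "generate_titration_dataset",
    "generate_inhibition_series",
]


@dataclass(frozen=True)
class CellLineEntry:
    """Published late-phase rate constant for one cell line / oxygen state."""

    name: str
    k_obs: float  # 1/s, late-phase (exofacial) first-order constant
    isoform: str  # exofacial isoform expressed by the line
    has_caii: bool  # intracellular CAII -> two-compartment, biphasic
    provenance: str


@dataclass(frozen=True)
class MembraneEntry:
    """Published membrane-ghost parameter set for one isoform."""

    name: str
    efficiency_max: float  # A, M^-1 s^-1, hydration direction
    pKa_apparent: float
    concentration: float  # mol/L active enzyme in the suspension
    n_replicates: int
    provenance: str


@dataclass(frozen=True)
class InhibitorEntry:
    """One sulfonamide inhibitor and how it acts."""

    name: str
    constant: float  # Ki (classical) or Kd (tight), mol/L
    mode: str
    permeant: bool
    provenance: str


# -- intracellular CAII placeholder (not a published value for these lines;
#    shapes only the early phase of UFH-001 curves) ---------------------------
CAII_DEFAULTS = MappingProxyType(
    {
        "efficiency_max": 1.2e8,  # M^-1 s^-1, typical cytosolic CAII
        "pKa_apparent": 6.9,
        "concentration": 20e-6,  # mol/L of cell water
    }
)


def _cell(name, k_obs, isoform, has_caii, where):
    return CellLineEntry(
        name=name,
        k_obs=k_obs,
        isoform=isoform,
        has_caii=has_caii,
        provenance=f"reported late-phase first-order rate constant, {where}",
    )


_CELL_LINES = {
    "UFH001_normoxic": _cell(
        "UFH001_normoxic", 0.70e-3, "CAIX", True, "normoxic UFH-001 whole cells"
    ),
    "UFH001_hypoxic": _cell(
        "UFH001_hypoxic", 1.17e-3, "CAIX", True, "hypoxic UFH-001 whole cells"
    ),
    "HBL100_normoxic": _cell(
        "HBL100_normoxic", 0.43e-3, "CAIX", False, "normoxic HBL-100 whole cells"
    ),
    "HBL100_hypoxic": _cell(
        "HBL100_hypoxic", 0.88e-3, "CAIX", False, "hypoxic HBL-100 whole cells"
    ),
    "T47D_normoxic": _cell(
        "T47D_normoxic", 4.32e-3, "CAXII", False, "normoxic T47D whole cells"
    ),
    "T47D_hypoxic": _cell(
        "T47D_hypoxic", 3.97e-3, "CAXII", False, "hypoxic T47D whole cells"
    ),
    "MCF7_normoxic": _cell(
        "MCF7_normoxic", 3.40e-3, "CAXII", False, "normoxic MCF7 whole cells"
    ),
    "MCF7_hypoxic": _cell(
        "MCF7_hypoxic", 1.97e-3, "CAXII", False, "hypoxic MCF7 whole cells"
    ),
}

_MEMBRANES = {
    "CAIX": MembraneEntry(
        name="CAIX",
        efficiency_max=3.8e7,
        pKa_apparent=6.2,
        concentration=4.1e-9,
        n_replicates=4,
        provenance=(
            "reported kcat_exch/K_eff_CO2 maximum, apparent pKa and active "
            "concentration for CAIX in hypoxic UFH-001 membrane ghosts"
        ),
    ),
    "CAXII": MembraneEntry(
        name="CAXII",
        efficiency_max=1.0e7,
        pKa_apparent=7.0,
        concentration=31.4e-9,
        n_replicates=3,
        provenance=(
            "reported kcat_exch/K_eff_CO2 maximum, apparent pKa and active "
            "concentration for CAXII in normoxic T47D membrane ghosts"
        ),
    ),
}

_INHIBITORS = {
    "N-3500": InhibitorEntry(
        name="N-3500",
        constant=12.6e-6,
        mode="classical",
        permeant=False,
        provenance="reported Ki of the impermeant sulfonamide N-3500",
    ),
    "ethoxzolamide": InhibitorEntry(
        name="ethoxzolamide",
        constant=1e-9,
        mode="tight",
        permeant=True,
        provenance=(
            "tight-binding sulfonamide used for active-site titration; Kd is a "
            "configurable default (1 nM), not a published value"
        ),
    ),
}


def standard_conditions(ph: float = 7.4, **overrides) -> AssayConditions:
    """The published assay conditions: 16 degC, 25 mM species, 2 mL, 5e5 cells/mL."""
    defaults = dict(
        ph=ph,
        temperature_c=16.0,
        total_carbon=0.025,
        vessel_volume=0.002,
        cell_density=5e5,
        label_enrichment=0.2,
    )
    defaults.update(overrides)
    return AssayConditions(**defaults)


@dataclass(frozen=True)
class FixtureSet:
    """Frozen registry of the published kinetic values driving every generator."""

    cell_lines: Mapping[str, CellLineEntry] = field(
        default_factory=lambda: MappingProxyType(_CELL_LINES)
    )
    membranes: Mapping[str, MembraneEntry] = field(
        default_factory=lambda: MappingProxyType(_MEMBRANES)
    )
    inhibitors: Mapping[str, InhibitorEntry] = field(
        default_factory=lambda: MappingProxyType(_INHIBITORS)
    )

    def get(self, dotted: str):
        """Dotted access, e.g. ``get("UFH001_hypoxic.k_obs")``."""
        entry_name, _, attr = dotted.partition(".")
        for registry in (self.cell_lines, self.membranes, self.inhibitors):
            if entry_name in registry:
                entry = registry[entry_name]
                return getattr(entry, attr) if attr else entry
        raise KeyError(f"unknown fixture entry {entry_name!r}")

    def numeric_entries(self) -> dict:
        """Every sourced numeric value with its provenance, for self-audit."""
        out = {}
        for name, e in self.cell_lines.items():
            out[f"{name}.k_obs"] = (e.k_obs, e.provenance)
        for name, e in self.membranes.items():
            out[f"{name}.efficiency_max"] = (e.efficiency_max, e.provenance)
            out[f"{name}.pKa"] = (e.pKa_apparent, e.provenance)
            out[f"{name}.concentration"] = (e.concentration, e.provenance)
        out["N-3500.Ki"] = (
            _INHIBITORS["N-3500"].constant,
            _INHIBITORS["N-3500"].provenance,
        )
        return out


_FIXTURES = FixtureSet()


def fixtures() -> FixtureSet:
    """The packaged fixture set (immutable)."""
    return _FIXTURES


def _inhibitor_constants() -> Mapping[str, InhibitorSpec]:
    return {
        e.name: InhibitorSpec(constant=e.constant, mode=e.mode, permeant=e.permeant)
        for e in _INHIBITORS.values()
    }


def _membrane_pool(entry: MembraneEntry, concentration: Optional[float] = None) -> EnzymePool:
    return EnzymePool(
        name=entry.name,
        compartment="exofacial",
        concentration=entry.concentration if concentration is None else concentration,
        efficiency_max=entry.efficiency_max,
        pKa_apparent=entry.pKa_apparent,
        inhibitor_constants=_inhibitor_constants(),
    )


def _caii_pool() -> EnzymePool:
    return EnzymePool(
        name="CAII",
        compartment="intracellular",
        concentration=CAII_DEFAULTS["concentration"],
        efficiency_max=CAII_DEFAULTS["efficiency_max"],
        pKa_apparent=CAII_DEFAULTS["pKa_apparent"],
        inhibitor_constants=_inhibitor_constants(),
    )


def build_layout(entry_name: str, conditions: Optional[AssayConditions] = None) -> Layout:
    """Layout for a fixture entry, calibrated where the entry is a rate constant.

    Membrane entries (CAIX, CAXII) become single-compartment ghost layouts at
    their published enzyme concentration.  Cell-line entries get their
    isoform's published (A, pKa) on the cell exterior, with the concentration
    calibrated so the model's slow eigenvalue equals the entry's published
    late-phase rate constant; lines with CAII become two-compartment.
    """
    conditions = conditions or standard_conditions()
    fx = fixtures()
    if entry_name in fx.membranes:
        entry = fx.membranes[entry_name]
        return Layout(pools=(_membrane_pool(entry),), name=f"{entry.name}-ghost")
    if entry_name in fx.cell_lines:
        entry = fx.cell_lines[entry_name]
        pools = [_membrane_pool(fx.membranes[entry.isoform], concentration=1e-9)]
        if entry.has_caii:
            pools.append(_caii_pool())
        layout = Layout(pools=tuple(pools), name=entry.name)
        return calibrate_activity_to_kobs(entry.k_obs, layout, conditions)
    raise KeyError(f"unknown fixture entry {entry_name!r}")


def generate_trace(
    entry_name: str,
    noise_sd: float = 0.0,
    seed: int = 0,
    conditions: Optional[AssayConditions] = None,
    times: Optional[Sequence[float]] = None,
    t_add: float = 120.0,
    inhibitors: Optional[Mapping[str, float]] = None,
    method: str = "expm",
) -> Trace:
    """Simulate one instrument trace for a fixture entry.

    0-500 s at 1 Hz by default, with the cell/ghost addition at ``t_add``.
    ``noise_sd`` is the relative sd of multiplicative log-normal noise on the
    atom fraction; the seed fully determines the output.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    conditions = conditions or standard_conditions()
    layout = build_layout(entry_name, conditions)
    trace = run_assay(
        layout,
        conditions,
        times=times,
        t_add=t_add,
        inhibitors=inhibitors,
        method=method,
        metadata={"fixture": entry_name, "seed": seed, "noise_sd": noise_sd},
    )
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        noisy = trace.alpha * np.exp(noise_sd * rng.standard_normal(len(trace.alpha)))
        trace = Trace(
            times=trace.times,
            alpha=np.clip(noisy, 0.0, 1.0),
            metadata=trace.metadata,
        )
    return trace


DEFAULT_PH_GRID = tuple(np.round(np.linspace(5.5, 8.5, 9), 6))


def generate_titration_dataset(
    enzyme_entry: str,
    ph_grid: Optional[Sequence[float]] = None,
    replicates: Optional[int] = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    conditions: Optional[AssayConditions] = None,
) -> list:
    """Hydration-direction efficiency vs pH for a membrane entry.

    Efficiencies come from the catalyzed-flux arithmetic (R1 / (E * [CO2]))
    at each grid pH, one :class:`TitrationCurve` per replicate, honoring the
    entry's published replicate count by default.
    """
    fx = fixtures()
    if enzyme_entry not in fx.membranes:
        raise KeyError(f"unknown membrane fixture entry {enzyme_entry!r}")
    entry = fx.membranes[enzyme_entry]
    grid = tuple(float(p) for p in (ph_grid if ph_grid is not None else DEFAULT_PH_GRID))
    if max(grid) - min(grid) < 1.5:
        raise ValueError("pH grid must span >= 1.5 units")
    n_rep = replicates if replicates is not None else entry.n_replicates
    conditions = conditions or standard_conditions()
    pool = _membrane_pool(entry)
    rng = np.random.default_rng(seed)
    curves = []
    for _ in range(n_rep):
        effs = []
        for ph in grid:
            cond = conditions.at_ph(ph)
            spec = speciate(cond)
            r1 = catalyzed_flux(pool, spec, ph)
            eff = r1 / (pool.concentration * spec.co2)
            if noise_sd > 0:
                eff *= float(np.exp(noise_sd * rng.standard_normal()))
            effs.append(eff)
        curves.append(
            TitrationCurve(
                ph_values=grid,
                efficiency=tuple(effs),
                direction="hydration",
                enzyme=entry.name,
            )
        )
    return curves


def default_inhibition_concentrations(enzyme_entry: str, inhibitor_entry: str) -> tuple:
    """A concentration grid spanning the titration for the given pair."""
    inh = fixtures().inhibitors[inhibitor_entry]
    if inh.mode == "classical":
        return (0.0, 1e-6, 3e-6, 1e-5, 3e-5, 1e-4, 3e-4, 1e-3)
    e = fixtures().membranes[enzyme_entry].concentration
    return tuple(e * f for f in (0.0, 0.1, 0.25, 0.5, 0.75, 1.0, 1.5, 3.0, 5.0))


def generate_inhibition_series(
    enzyme_entry: str,
    inhibitor_entry: str,
    concentrations: Optional[Sequence[float]] = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> InhibitionSeries:
    """Normalized activity vs inhibitor concentration for a membrane entry."""
    fx = fixtures()
    entry = fx.membranes[enzyme_entry]
    inh = fx.inhibitors[inhibitor_entry]
    if concentrations is None:
        concentrations = default_inhibition_concentrations(enzyme_entry, inhibitor_entry)
    conc = tuple(float(c) for c in concentrations)
    if 0.0 not in conc:
        raise ValueError("concentrations must include 0")
    rng = np.random.default_rng(seed)
    acts = []
    for c in conc:
        a = fractional_activity(entry.concentration, c, inh.constant, mode=inh.mode)
        if noise_sd > 0:
            a *= float(np.exp(noise_sd * rng.standard_normal()))
        acts.append(a)
    return InhibitionSeries(
        inhibitor=inh.name,
        concentrations=conc,
        fractional_activities=tuple(acts),
        enzyme=entry.name,
        noise_sd=noise_sd,
    )
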