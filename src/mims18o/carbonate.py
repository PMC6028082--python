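"""Equilibrium speciation of the CO2/bicarbonate buffer and uncatalyzed rates.

The assay takes place at chemical equilibrium: total dissolved carbon is
partitioned between CO2(aq) (lumped with H2CO3) and HCO3- by a single apparent
first dissociation constant (Henderson-Hasselbalch).  Carbonate ion is
neglected: at the highest assay pH used here (7.9) it is below ~1.5% of the
species and its 18O bookkeeping would triple the state space for no measurable
effect on the fitted constants.

All concentrations are mol/L, temperatures degrees Celsius, rates 1/s.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Union

import yaml

__all__ = [
    "DEFAULT_PK1",
    "DEFAULT_KH_16C",
    "DEFAULT_Q10",
    "AssayConditions",
    "CarbonateSpeciation",
    "UncatalyzedRates",
    "speciate",
    "uncatalyzed_rates",
    "load_conditions",
]

#: Apparent first dissociation constant of CO2(aq)+H2CO3 at 16 degC in dilute
#: buffer.  Configurable everywhere it is used; the pH 6.8 vs 7.4 fold-change
#: prediction is sensitive to it.
DEFAULT_PK1 = 6.35

#: Uncatalyzed CO2 hydration pseudo-first-order constant at 16 degC, 1/s.
DEFAULT_KH_16C = 1.2e-3

#: Q10 temperature coefficient for the uncatalyzed hydration rate.
DEFAULT_Q10 = 2.0

PH_MIN, PH_MAX = 5.0, 9.0


@dataclass(frozen=True)
class AssayConditions:
    """Shared chemical context of one 18O-exchange run.

    Defaults reproduce the standard assay: 2 mL of bicarbonate-free medium at
    16 degC holding 25 mM total labeled CO2 species, cells added at
    5e5 cells/mL.  ``label_enrichment`` is the initial 18O atom fraction of
    the dissolved carbon pool (a fixture parameter; the kinetics are linear in
    label so fitted rate constants do not depend on it).
    """

    ph: float
    temperature_c: float = 16.0
    total_carbon: float = 0.025
    vessel_volume: float = 0.002
    cell_density: float = 5e5
    label_enrichment: float = 0.2

    def __post_init__(self) -> None:
        if not (PH_MIN <= self.ph <= PH_MAX):
            raise ValueError(
                f"pH {self.ph} outside supported range [{PH_MIN}, {PH_MAX}]"
            )
        if self.total_carbon <= 0:
            raise ValueError("total_carbon must be positive")
        if self.vessel_volume <= 0:
            raise ValueError("vessel_volume must be positive")
        if not (0.0 <= self.label_enrichment <= 1.0):
            raise ValueError("label_enrichment must lie in [0, 1]")
        if self.cell_density is not None and self.cell_density < 0:
            raise ValueError("cell_density must be non-negative")

    def at_ph(self, ph: float) -> "AssayConditions":
        return replace(self, ph=ph)


@dataclass(frozen=True)
class CarbonateSpeciation:
    """Two-species partition of total carbon at equilibrium."""

    co2: float
    hco3: float
    pk1_apparent: float

    @property
    def total(self) -> float:
        return self.co2 + self.hco3


@dataclass(frozen=True)
class UncatalyzedRates:
    """Background interconversion constants (no enzyme).

    ``k_h`` applies to CO2 (hydration), ``k_d`` to HCO3- (dehydration); they
    are tied so the two chemical fluxes balance at equilibrium:
    k_h * [CO2] == k_d * [HCO3-].
    """

    k_h: float
    k_d: float


def speciate(
    conditions: AssayConditions, pk1_apparent: float = DEFAULT_PK1
) -> CarbonateSpeciation:
    """Partition total carbon between CO2 and HCO3- at the assay pH.

    Henderson-Hasselbalch with a single apparent pK1:
    [HCO3-]/[CO2] = 10**(pH - pK1).
    """
    ratio = 10.0 ** (conditions.ph - pk1_apparent)
    co2 = conditions.total_carbon / (1.0 + ratio)
    hco3 = conditions.total_carbon - co2
    return CarbonateSpeciation(co2=co2, hco3=hco3, pk1_apparent=pk1_apparent)


def uncatalyzed_rates(
    speciation: CarbonateSpeciation,
    temperature_c: float = 16.0,
    k_h_16c: float = DEFAULT_KH_16C,
    q10: float = DEFAULT_Q10,
) -> UncatalyzedRates:
    """Uncatalyzed hydration/dehydration constants at the assay temperature.

    The hydration constant follows a Q10 law around 16 degC; the dehydration
    constant is fixed by flux balance, k_d = k_h * co2/hco3, so the chemical
    system stays at equilibrium.  These background rates are what remains when
    all enzyme activity is inhibited.
    """
    if speciation.hco3 <= 0:
        raise ValueError("dehydration constant undefined for hco3 <= 0")
    k_h = k_h_16c * q10 ** ((temperature_c - 16.0) / 10.0)
    k_d = k_h * speciation.co2 / speciation.hco3
    return UncatalyzedRates(k_h=k_h, k_d=k_d)


_CONDITION_KEYS = {
    "ph": ("ph", 1.0),
    "temperature_c": ("temperature_c", 1.0),
    "total_carbon_mM": ("total_carbon", 1e-3),
    "total_carbon_M": ("total_carbon", 1.0),
    "vessel_volume_mL": ("vessel_volume", 1e-3),
    "vessel_volume_L": ("vessel_volume", 1.0),
    "cell_density_per_mL": ("cell_density", 1.0),
    "label_enrichment": ("label_enrichment", 1.0),
}


def load_conditions(path: Union[str, Path]) -> AssayConditions:
    """Read assay conditions from a flat YAML/JSON key-value file.

    Recognised keys: ph, temperature_c, total_carbon_mM (or total_carbon_M),
    vessel_volume_mL (or vessel_volume_L), cell_density_per_mL,
    label_enrichment.  Unknown keys are rejected to catch typos.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        raw = json.loads(text)
    else:
        raw = yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: expected a flat key-value mapping")
    kwargs = {}
    for key, value in raw.items():
        if key not in _CONDITION_KEYS:
            raise ValueError(f"{path}: unknown condition key {key!r}")
        field, scale = _CONDITION_KEYS[key]
        kwargs[field] = float(value) * scale
    if "ph" not in kwargs:
        raise ValueError(f"{path}: missing required key 'ph'")
    return AssayConditions(**kwargs)
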