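"""Energy balance of co-stream processing: inputs, biogas/CHP output, ratio.

The system energy balance is the difference between the energy recovered
from the biomass (here: CHP heat plus electricity from co-digestion biogas)
and everything spent getting it there:

    E_final = E_BM - E_input

where the total input is a sum over technological operations, each split
into a direct part (fuel, electricity, heat consumed by the operation) and
an indirect part (embodied energy of machinery and consumables):

    E_input = sum_i E_TEi,      E_TEi = E_di + E_indi

All module-level quantities are MJ per tonne of raw material (t_RM) unless
stated otherwise; electricity is tracked separately in kWh/t_RM and
converted at 3.6 MJ/kWh.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Optional, Sequence

import pandas as pd
from pydantic import BaseModel, Field

from .core import MJ_PER_KWH, BiogasPlantSpec

__all__ = [
    "EnergyEntry",
    "EnergyLedger",
    "EnergyBalanceResult",
    "ChpOutput",
    "chp_output",
    "biomass_energy",
    "total_energy_input",
    "energy_balance",
    "transport_energy",
    "electricity_balance",
]


class EnergyEntry(BaseModel):
    """Direct + indirect energy demand of one technological operation."""

    operation: str = Field(min_length=1)
    direct: float = Field(ge=0.0, description="MJ/t_RM")
    indirect: float = Field(ge=0.0, description="MJ/t_RM")
    #: True when the entry closes the ledger to a published aggregate rather
    #: than coming from an itemised coefficient.
    reconciliation: bool = False

    model_config = {"frozen": True}

    @property
    def total(self) -> float:
        return self.direct + self.indirect


class EnergyLedger(BaseModel):
    """Itemised energy inputs of one concept."""

    entries: tuple[EnergyEntry, ...]

    model_config = {"frozen": True}

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def e_input(self) -> float:
        return total_energy_input(self)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "operation": e.operation,
                    "direct_MJ_per_tRM": e.direct,
                    "indirect_MJ_per_tRM": e.indirect,
                    "total_MJ_per_tRM": e.total,
                    "reconciliation": e.reconciliation,
                }
                for e in self.entries
            ]
        )


class ChpOutput(BaseModel):
    """Biogas plant output for a given feed."""

    biogas_m3: float = Field(ge=0.0)
    methane_m3: float = Field(ge=0.0)
    heat_kwh: float = Field(ge=0.0)
    electricity_kwh: float = Field(ge=0.0)

    model_config = {"frozen": True}


def chp_output(residue_mass: float, manure_mass: float, spec: BiogasPlantSpec) -> ChpOutput:
    """Biogas, methane and CHP heat/electricity for a co-digested feed.

    Biogas volume follows the whole feed mixture (residue + manure) times
    the specific yield; CHP heat and electricity scale linearly with the
    residue throughput relative to the spec's basis throughput.  A feed
    ratio off the spec's design ratio is accepted with a warning — the
    yield figure was measured at that ratio.
    """
    if residue_mass < 0 or manure_mass < 0:
        raise ValueError("feed masses must be non-negative")
    if residue_mass > 0:
        ratio = manure_mass / residue_mass
        if abs(ratio - spec.residue_to_manure_ratio) > 0.01 * spec.residue_to_manure_ratio:
            warnings.warn(
                f"feed ratio 1:{ratio:.2f} deviates from the design ratio "
                f"1:{spec.residue_to_manure_ratio:g}; yield and CHP figures "
                "were established at the design ratio",
                stacklevel=2,
            )
    biogas = (residue_mass + manure_mass) * spec.biogas_yield
    scale = residue_mass / spec.basis_residue_t
    return ChpOutput(
        biogas_m3=biogas,
        methane_m3=biogas * spec.methane_fraction,
        heat_kwh=spec.heat_output * scale,
        electricity_kwh=spec.electricity_output * scale,
    )


def biomass_energy(spec: Optional[BiogasPlantSpec]) -> float:
    """Recovered biomass energy E_BM in MJ/t_RM: CHP heat + electricity.

    Concepts without a biogas branch recover no energy (the products carry
    their chemical energy out of the battery limits as goods, not fuel).
    """
    if spec is None:
        return 0.0
    return (spec.heat_output + spec.electricity_output) * MJ_PER_KWH


def total_energy_input(ledger: EnergyLedger) -> float:
    """Total energy input E_input: exact sum of direct+indirect per operation."""
    if len(ledger.entries) == 0:
        raise ValueError("energy ledger is empty")
    return sum(e.direct + e.indirect for e in ledger.entries)


class EnergyBalanceResult(BaseModel):
    """System energy balance of one concept, MJ/t_RM."""

    e_bm: float
    e_input: float
    e_final: float
    #: E_BM / E_input; None when E_input is zero (undefined, not infinite).
    ratio: Optional[float]
    electricity_generated: Optional[float] = Field(default=None, description="kWh/t_RM")
    electricity_consumed: Optional[float] = Field(default=None, description="kWh/t_RM")
    electricity_useful: Optional[float] = Field(default=None, description="kWh/t_RM")

    model_config = {"frozen": True}


def energy_balance(
    e_bm: float,
    ledger: EnergyLedger,
    *,
    electricity_generated: Optional[float] = None,
    electricity_consumed: Optional[float] = None,
) -> EnergyBalanceResult:
    """E_final = E_BM - E_input, with the input/output ratio.

    The ratio is reported to full precision; round to one decimal when
    comparing with published figures.
    """
    if e_bm < 0:
        raise ValueError("e_bm must be non-negative")
    e_input = total_energy_input(ledger)
    useful = None
    if electricity_generated is not None and electricity_consumed is not None:
        useful = electricity_generated - electricity_consumed
    return EnergyBalanceResult(
        e_bm=e_bm,
        e_input=e_input,
        e_final=e_bm - e_input,
        ratio=(e_bm / e_input) if e_input > 0 else None,
        electricity_generated=electricity_generated,
        electricity_consumed=electricity_consumed,
        electricity_useful=useful,
    )


def transport_energy(mass: float, distance: float, coeff: float) -> float:
    """Transport energy in MJ: mass (t) x distance (km) x coefficient (MJ/t/km)."""
    if mass < 0 or distance < 0 or coeff < 0:
        raise ValueError("mass, distance and coefficient must be non-negative")
    return mass * distance * coeff


def electricity_balance(
    generated: float, consumers: Sequence[tuple[str, float]]
) -> float:
    """Net useful (sellable) electricity in kWh/t_RM.

    Negative net means the concept purchases power from the grid.
    """
    if generated < 0 or any(q < 0 for _, q in consumers):
        raise ValueError("generation and consumption must be non-negative")
    return generated - sum(q for _, q in consumers)
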