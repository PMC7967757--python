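"""Domain types and deterministic stream arithmetic shared by all stages.

All per-tonne process coefficients are keyed to ``t_RM``: one tonne of fish
co-stream (heads, backbones, viscera left after filleting) entering the
processing plant.  A :class:`ProcessBalance` is a fixed coefficient table —
no thermodynamics, no kinetics — and every downstream quantity (energy,
cost, revenue) is obtained by scaling those coefficients linearly with plant
capacity.

Quantities are stored in their declared units and converted only at
computation boundaries (kg -> t at 1e-3, kWh -> MJ at 3.6).
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Iterable, Literal, Mapping, Optional

import pandas as pd
import yaml
from pydantic import BaseModel, Field, model_validator

__all__ = [
    "KG_PER_T",
    "MJ_PER_KWH",
    "METHANE_LHV_MJ_PER_M3",
    "EUR_TO_USD",
    "Unit",
    "Role",
    "UnknownUnitError",
    "MissingPriceError",
    "StreamCoefficient",
    "ProcessBalance",
    "BiogasPlantSpec",
    "FeedstockComposition",
    "FarmSpec",
    "Price",
    "PriceTable",
    "CapexSpec",
    "OpexFactors",
    "ScenarioConfig",
    "AnnualFlow",
    "AnnualFlows",
    "MassClosure",
    "annualize",
    "mass_closure",
    "load_scenario",
    "save_scenario",
]

KG_PER_T = 1000.0
MJ_PER_KWH = 3.6
#: Lower heating value of methane, MJ per normal m^3; used only as a sanity
#: bound on CHP output, never as a conversion in the balance itself.
METHANE_LHV_MJ_PER_M3 = 35.9
#: Display-only currency factor; all computation is carried out in USD.
EUR_TO_USD = 1.1

Unit = Literal["kg/t_RM", "t/t_RM", "kWh/t_RM", "m3/t_RM"]
Role = Literal["input", "output"]

#: Annual-flow unit implied by each per-tonne unit (kg coefficients are
#: reported as tonnes per year).
_ANNUAL_UNIT: Mapping[str, str] = {
    "kg/t_RM": "t/a",
    "t/t_RM": "t/a",
    "kWh/t_RM": "kWh/a",
    "m3/t_RM": "m3/a",
}


class UnknownUnitError(ValueError):
    """A stream carries a unit outside the closed per-tonne unit set."""


class MissingPriceError(KeyError):
    """A bought or sold stream has no entry in the price table."""

    def __init__(self, name: str) -> None:
        super().__init__(name)
        self.name = name

    def __str__(self) -> str:  # KeyError quotes its arg; keep it readable
        return f"no price listed for stream {self.name!r}"


class StreamCoefficient(BaseModel):
    """One input or output of a process, per tonne of raw material."""

    name: str = Field(min_length=1)
    role: Role
    quantity: float = Field(ge=0.0)
    unit: Unit

    model_config = {"frozen": True}


class ProcessBalance(BaseModel):
    """Per-tonne input/output coefficient table of one processing concept.

    Invariants: exactly one ``fish_co_stream`` input of 1000 kg/t_RM (the
    normalisation basis), unique (name, role) pairs, and kg-denominated
    output mass never exceeding kg-denominated input mass — the difference
    is evaporated water and incidental losses.
    """

    concept_id: str = Field(min_length=1)
    streams: tuple[StreamCoefficient, ...]

    model_config = {"frozen": True}

    @model_validator(mode="after")
    def _check(self) -> "ProcessBalance":
        seen = set()
        for s in self.streams:
            key = (s.name, s.role)
            if key in seen:
                raise ValueError(f"duplicate stream {key} in balance {self.concept_id}")
            seen.add(key)
        raw = [
            s for s in self.streams
            if s.role == "input" and s.name == "fish_co_stream"
        ]
        if len(raw) != 1 or raw[0].unit != "kg/t_RM" or raw[0].quantity != KG_PER_T:
            raise ValueError(
                f"balance {self.concept_id} must contain exactly one "
                "fish_co_stream input of 1000 kg/t_RM"
            )
        mass_in = sum(
            s.quantity for s in self.streams
            if s.role == "input" and s.unit == "kg/t_RM"
        )
        mass_out = sum(
            s.quantity for s in self.streams
            if s.role == "output" and s.unit == "kg/t_RM"
        )
        if mass_out > mass_in * (1.0 + 1e-9):
            raise ValueError(
                f"balance {self.concept_id}: material outputs "
                f"({mass_out:.1f} kg/t_RM) exceed inputs ({mass_in:.1f} kg/t_RM)"
            )
        return self

    def inputs(self) -> tuple[StreamCoefficient, ...]:
        return tuple(s for s in self.streams if s.role == "input")

    def outputs(self) -> tuple[StreamCoefficient, ...]:
        return tuple(s for s in self.streams if s.role == "output")

    def get(self, name: str, role: Role) -> Optional[StreamCoefficient]:
        for s in self.streams:
            if s.name == name and s.role == role:
                return s
        return None


class BiogasPlantSpec(BaseModel):
    """Co-digestion plant operating point, keyed to one tonne of raw material.

    The plant co-digests solid fish residue with liquid cattle manure (one
    part residue to ``residue_to_manure_ratio`` parts manure by mass) in a
    wet mesophilic single-stage digester; the biogas drives a CHP
    micro-turbine.  ``heat_output`` / ``electricity_output`` /
    ``fertiliser_output`` are CHP and digestate yields per t_RM at the basis
    throughput ``basis_residue_t`` (t residue fed per t_RM); the plant model
    scales them linearly with residue throughput.
    """

    residue_to_manure_ratio: float = Field(gt=0.0, default=5.0)
    biogas_yield: float = Field(ge=0.0, description="m3 biogas per t of feed mixture")
    methane_fraction: float = Field(gt=0.0, lt=1.0)
    heat_output: float = Field(ge=0.0, description="kWh/t_RM at basis throughput")
    electricity_output: float = Field(ge=0.0, description="kWh/t_RM at basis throughput")
    fertiliser_output: float = Field(ge=0.0, description="kg digestate/t_RM")
    basis_residue_t: float = Field(gt=0.0, default=1.0, description="t residue per t_RM")
    digester_volume: float = Field(ge=0.0, default=0.0, description="m3")
    organic_loading_rate: float = Field(ge=0.0, default=0.0, description="kg VS/m3/d")
    ts_input: float = Field(ge=0.0, le=1.0, default=0.0, description="wt. fraction")
    self_consumption_energy: float = Field(ge=0.0, default=0.0, description="MJ/t_RM")
    self_consumption_electricity: float = Field(ge=0.0, default=0.0, description="kWh/t_RM")

    model_config = {"frozen": True}

    @model_validator(mode="after")
    def _energy_sane(self) -> "BiogasPlantSpec":
        feed_t = self.basis_residue_t * (1.0 + self.residue_to_manure_ratio)
        methane_m3 = feed_t * self.biogas_yield * self.methane_fraction
        out_mj = (self.heat_output + self.electricity_output) * MJ_PER_KWH
        if out_mj > methane_m3 * METHANE_LHV_MJ_PER_M3 * (1.0 + 1e-9):
            raise ValueError(
                "CHP heat+electricity exceeds the chemical energy of the "
                f"methane produced ({out_mj:.0f} MJ/t_RM > "
                f"{methane_m3 * METHANE_LHV_MJ_PER_M3:.0f} MJ/t_RM)"
            )
        return self


class FeedstockComposition(BaseModel):
    """Chemical composition of a digester feedstock (wet-basis TS, rest on TS)."""

    ts: float = Field(ge=0.0, le=100.0, description="total solids, wt.%")
    vs_of_ts: float = Field(ge=0.0, le=100.0, description="volatile solids, wt.% of TS")
    organic_c: float = Field(ge=0.0, le=100.0, description="organic carbon, wt.% of TS")
    n: float = Field(ge=0.0, description="total nitrogen, mg/kg")
    p: float = Field(ge=0.0, description="total phosphorus, mg/kg")
    k: float = Field(ge=0.0, description="total potassium, mg/kg")
    fat: float = Field(ge=0.0, le=100.0, description="fat, wt.%")
    minor_elements: dict[str, float] = Field(default_factory=dict, description="mg/kg unless noted")

    model_config = {"frozen": True}


class FarmSpec(BaseModel):
    """Fertilisation scheme of the receiving farms (barley on arable land).

    Without digestate, each farm splits its area into a manured part
    (cattle manure plus a reduced mixed-fertiliser top-up) and a
    mineral-only part; the two application rates are in kg of mixed
    mineral fertiliser per hectare.
    """

    n_farms: int = Field(ge=0)
    area_per_farm: float = Field(ge=0.0, description="ha")
    nutrient_requirement: dict[str, float] = Field(
        default_factory=dict, description="kg/ha, keys N/P/K"
    )
    manure_per_farm: float = Field(ge=0.0, description="t/a")
    manure_application_rate: float = Field(ge=0.0, description="t/ha")
    mixed_fertiliser_rate_manured: float = Field(ge=0.0, description="kg/ha")
    mixed_fertiliser_rate_mineral_only: float = Field(ge=0.0, description="kg/ha")
    manured_area: float = Field(ge=0.0, description="ha per farm")
    mineral_only_area: float = Field(ge=0.0, description="ha per farm")

    model_config = {"frozen": True}

    @model_validator(mode="after")
    def _areas(self) -> "FarmSpec":
        if abs(self.manured_area + self.mineral_only_area - self.area_per_farm) > 1e-6:
            raise ValueError("manured_area + mineral_only_area must equal area_per_farm")
        return self


PriceBasis = Literal["per_t", "per_kg", "per_MWh", "per_m3"]

#: price basis compatible with each stream unit, with the factor converting
#: an annual flow (t/a, kWh/a or m3/a) into the priced quantity.
_PRICE_CONVERSION: Mapping[tuple[str, str], float] = {
    ("kg/t_RM", "per_t"): 1.0,
    ("kg/t_RM", "per_kg"): KG_PER_T,
    ("t/t_RM", "per_t"): 1.0,
    ("kWh/t_RM", "per_MWh"): 1.0 / 1000.0,
    ("m3/t_RM", "per_m3"): 1.0,
}


class Price(BaseModel):
    """A unit price in USD with its quantity basis."""

    value: float = Field(gt=0.0)
    basis: PriceBasis = "per_t"

    model_config = {"frozen": True}


class PriceTable(BaseModel):
    """Unit prices (USD) for every stream a scenario buys or sells."""

    prices: dict[str, Price]

    model_config = {"frozen": True}

    def get(self, name: str) -> Price:
        try:
            return self.prices[name]
        except KeyError:
            raise MissingPriceError(name) from None

    def value(self, name: str) -> float:
        return self.get(name).value

    def __contains__(self, name: str) -> bool:
        return name in self.prices

    def replace(self, new_values: Mapping[str, float]) -> "PriceTable":
        """Return a copy with the named price values replaced."""
        merged = dict(self.prices)
        for name, value in new_values.items():
            if name not in merged:
                raise MissingPriceError(name)
            merged[name] = Price(value=value, basis=merged[name].basis)
        return PriceTable(prices=merged)

    def annual_value(self, name: str, annual_quantity: float, unit: Unit) -> float:
        """USD per year for an annual flow expressed in the unit's annual form."""
        price = self.get(name)
        try:
            factor = _PRICE_CONVERSION[(unit, price.basis)]
        except KeyError:
            raise UnknownUnitError(
                f"price basis {price.basis!r} incompatible with stream unit {unit!r}"
            ) from None
        return annual_quantity * factor * price.value


class CapexSpec(BaseModel):
    """Investment costs: processing plant plus farm-scale biogas plants."""

    processing_investment: float = Field(ge=0.0, description="USD")
    biogas_investment_per_farm: float = Field(ge=0.0, default=0.0, description="USD")
    n_biogas_plants: int = Field(ge=0, default=0)

    model_config = {"frozen": True}

    @property
    def total_investment(self) -> float:
        return self.processing_investment + self.n_biogas_plants * self.biogas_investment_per_farm


class OpexFactors(BaseModel):
    """Labour, maintenance, depreciation and logistics cost factors."""

    operators: int = Field(ge=0)
    salary: float = Field(ge=0.0, description="USD/a")
    indirect_labour_frac: float = Field(ge=0.0, le=1.0, description="fraction of salary")
    maintenance_frac: float = Field(ge=0.0, le=1.0, description="fraction of investment/a")
    depreciation_time: float = Field(gt=0.0, description="a")
    other_indirect_frac: float = Field(ge=0.0, le=1.0, description="fraction of investment/a")
    logistics_rate: float = Field(ge=0.0, description="USD/t/km")
    distance_km: float = Field(ge=0.0, description="km")

    model_config = {"frozen": True}


class ScenarioConfig(BaseModel):
    """One processing concept bound to capacity, prices, capex and farm spec.

    ``digestate_fertiliser_offset_t`` is the tonnage of purchased mineral
    fertiliser displaced per year by digestate returned to the fields; it is
    clamped to the farm demand.
    """

    concept_id: str
    capacity: float = Field(ge=0.0, description="t raw material/a")
    operating_hours: float = Field(ge=0.0, default=3000.0, description="h/a")
    balance: ProcessBalance
    biogas: Optional[BiogasPlantSpec] = None
    farm: FarmSpec
    prices: PriceTable
    capex: CapexSpec
    opex: OpexFactors
    transport_distance_km: float = Field(ge=0.0, default=100.0)
    digestate_fertiliser_offset_t: float = Field(ge=0.0, default=0.0, description="t/a")

    model_config = {"frozen": True}

    @model_validator(mode="after")
    def _biogas_iff_residue(self) -> "ScenarioConfig":
        has_residue = self.balance.get("residue", "output") is not None
        if has_residue and self.biogas is None:
            raise ValueError("scenario produces a residue stream but has no biogas plant spec")
        if not has_residue and self.biogas is not None:
            raise ValueError("scenario has a biogas plant spec but produces no residue stream")
        return self

    @property
    def residue_coefficient(self) -> float:
        """Residue output in kg per t_RM (0 when the concept leaves none)."""
        s = self.balance.get("residue", "output")
        return s.quantity if s is not None else 0.0


class AnnualFlow(BaseModel):
    """One stream scaled from per-tonne coefficient to annual quantity."""

    name: str
    role: Role
    unit: Unit
    per_t_rm: float
    annual: float
    annual_unit: str

    model_config = {"frozen": True}


class AnnualFlows(BaseModel):
    """Annual stream quantities of a scenario, indexable by (name, role)."""

    flows: tuple[AnnualFlow, ...]

    model_config = {"frozen": True}

    def __iter__(self):
        return iter(self.flows)

    def __len__(self) -> int:
        return len(self.flows)

    def get(self, name: str, role: Role) -> Optional[AnnualFlow]:
        for f in self.flows:
            if f.name == name and f.role == role:
                return f
        return None

    def annual(self, name: str, role: Role) -> float:
        f = self.get(name, role)
        return f.annual if f is not None else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "stream": f.name,
                    "role": f.role,
                    "unit": f.unit,
                    "per_tRM": f.per_t_rm,
                    "annual": f.annual,
                    "annual_unit": f.annual_unit,
                }
                for f in self.flows
            ]
        )


def annualize(balance: ProcessBalance, capacity: float) -> AnnualFlows:
    """Scale per-tonne coefficients to annual flows at the given capacity.

    kg-denominated coefficients are reported as t/a; all other units keep
    their per-tonne unit on an annual basis.  Linear in ``capacity``.
    """
    if capacity < 0:
        raise ValueError("capacity must be non-negative")
    flows = []
    for s in balance.streams:
        if s.unit not in _ANNUAL_UNIT:  # pragma: no cover - typed out upstream
            raise UnknownUnitError(f"unknown unit {s.unit!r} on stream {s.name!r}")
        scale = capacity / KG_PER_T if s.unit == "kg/t_RM" else capacity
        flows.append(
            AnnualFlow(
                name=s.name,
                role=s.role,
                unit=s.unit,
                per_t_rm=s.quantity,
                annual=s.quantity * scale,
                annual_unit=_ANNUAL_UNIT[s.unit],
            )
        )
    return AnnualFlows(flows=tuple(flows))


class MassClosure(BaseModel):
    """Material closure of a balance over its kg-denominated streams."""

    mass_in: float = Field(description="kg/t_RM")
    mass_out: float = Field(description="kg/t_RM")
    ratio: float
    unaccounted: float = Field(description="kg/t_RM lost to evaporation/losses")

    model_config = {"frozen": True}


def mass_closure(balance: ProcessBalance) -> MassClosure:
    """Mass out / mass in over kg-denominated streams.

    Utility streams carried in t, kWh or m3 (steam, electricity, water) are
    excluded: they are not incorporated into products.  The unaccounted
    remainder is evaporated water and incidental losses.
    """
    mass_in = sum(
        s.quantity for s in balance.streams
        if s.role == "input" and s.unit == "kg/t_RM"
    )
    mass_out = sum(
        s.quantity for s in balance.streams
        if s.role == "output" and s.unit == "kg/t_RM"
    )
    if mass_in <= 0:
        raise ValueError(f"balance {balance.concept_id} has no material input")
    if mass_out > mass_in * (1.0 + 1e-9):
        raise ValueError("material outputs exceed inputs")
    return MassClosure(
        mass_in=mass_in,
        mass_out=mass_out,
        ratio=mass_out / mass_in,
        unaccounted=mass_in - mass_out,
    )


def save_scenario(scenario: ScenarioConfig, path: str | Path) -> None:
    """Write a scenario as JSON or YAML depending on the file suffix."""
    path = Path(path)
    data = scenario.model_dump(mode="json")
    if path.suffix.lower() in {".yaml", ".yml"}:
        path.write_text(yaml.safe_dump(data, sort_keys=False))
    else:
        path.write_text(json.dumps(data, indent=2))


def load_scenario(path: str | Path) -> ScenarioConfig:
    """Load a scenario written by :func:`save_scenario`."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in {".yaml", ".yml"}:
        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    return ScenarioConfig.model_validate(data)
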