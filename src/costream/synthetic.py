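"""Random scenario generator for property-based testing.

Generated scenarios have the same structural shape as the study concepts —
one fish co-stream input of 1000 kg/t_RM, a random product slate whose
material outputs never exceed the input mass (closure holds by
construction), optional utility inputs, an optional residue stream feeding
a farm-scale co-digestion branch, a farm fertilisation scheme, and a full
price/capex/opex configuration.  They are *not* calibrated to any real
process: they exist so that accounting identities (statement balance, mass
closure, energy balance, linearity) can be exercised over a wide random
family, independently of the published concept fixtures.

Generation is a pure function of the spec (seeded NumPy generator), so the
same spec always yields the identical scenario.
"""

from __future__ import annotations

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .core import (
    BiogasPlantSpec,
    CapexSpec,
    FarmSpec,
    KG_PER_T,
    METHANE_LHV_MJ_PER_M3,
    MJ_PER_KWH,
    OpexFactors,
    Price,
    PriceTable,
    ProcessBalance,
    ScenarioConfig,
    StreamCoefficient,
)

__all__ = ["SyntheticScenarioSpec", "generate_scenario"]


def _check_range(name: str, rng_pair: tuple[float, float]) -> None:
    lo, hi = rng_pair
    if lo > hi:
        raise ValueError(f"infeasible {name}: min {lo} > max {hi}")


class SyntheticScenarioSpec(BaseModel):
    """Knobs of the random scenario family."""

    seed: int = 0
    n_products: int = Field(ge=1, default=3)
    closure_range: tuple[float, float] = (0.3, 0.95)
    price_range: tuple[float, float] = (50.0, 4000.0)
    capex_range: tuple[float, float] = (5e5, 2e7)
    capacity_range: tuple[float, float] = (1000.0, 20000.0)
    has_biogas: bool = True
    has_residue: bool = True

    model_config = {"frozen": True}

    @model_validator(mode="after")
    def _validate(self) -> "SyntheticScenarioSpec":
        for name in ("closure_range", "price_range", "capex_range", "capacity_range"):
            _check_range(name, getattr(self, name))
        if self.has_biogas != self.has_residue:
            raise ValueError(
                "has_biogas must equal has_residue: the co-digestion branch "
                "exists exactly when the process leaves a residue"
            )
        return self


def generate_scenario(spec: SyntheticScenarioSpec) -> ScenarioConfig:
    """Draw one reproducible random scenario satisfying all core validators."""
    rng = np.random.default_rng(spec.seed)

    closure = rng.uniform(*spec.closure_range)
    n_slots = spec.n_products + (1 if spec.has_residue else 0)
    shares = rng.dirichlet(np.ones(n_slots))
    masses = shares * closure * KG_PER_T

    streams = [
        StreamCoefficient(
            name="fish_co_stream", role="input", quantity=KG_PER_T, unit="kg/t_RM"
        ),
        StreamCoefficient(
            name="steam", role="input", quantity=rng.uniform(0.1, 2.0), unit="t/t_RM"
        ),
        StreamCoefficient(
            name="electricity", role="input", quantity=rng.uniform(5.0, 100.0),
            unit="kWh/t_RM",
        ),
    ]
    product_names = [f"product_{i:02d}" for i in range(spec.n_products)]
    for name, mass in zip(product_names, masses):
        streams.append(
            StreamCoefficient(name=name, role="output", quantity=mass, unit="kg/t_RM")
        )
    # when a residue is present, the last dirichlet slot is its mass and the
    # zip above consumed only the first n_products slots
    residue_kg = masses[-1] if spec.has_residue else 0.0
    if spec.has_residue:
        streams.append(
            StreamCoefficient(
                name="residue", role="output", quantity=residue_kg, unit="kg/t_RM"
            )
        )
    balance = ProcessBalance(concept_id=f"synthetic-{spec.seed}", streams=tuple(streams))

    biogas = None
    if spec.has_residue:
        ratio = rng.uniform(3.0, 8.0)
        yield_m3 = rng.uniform(50.0, 120.0)
        methane = rng.uniform(0.50, 0.70)
        basis_residue = max(residue_kg / KG_PER_T, 1e-6)
        feed_t = basis_residue * (1.0 + ratio)
        methane_energy = feed_t * yield_m3 * methane * METHANE_LHV_MJ_PER_M3
        chp_eff = rng.uniform(0.40, 0.85)
        heat_share = rng.uniform(0.40, 0.70)
        total_kwh = methane_energy * chp_eff / MJ_PER_KWH
        biogas = BiogasPlantSpec(
            residue_to_manure_ratio=ratio,
            biogas_yield=yield_m3,
            methane_fraction=methane,
            heat_output=total_kwh * heat_share,
            electricity_output=total_kwh * (1.0 - heat_share),
            fertiliser_output=feed_t * KG_PER_T * rng.uniform(0.80, 0.95),
            basis_residue_t=basis_residue,
            digester_volume=rng.uniform(500.0, 5000.0),
            organic_loading_rate=rng.uniform(1.0, 4.0),
            ts_input=rng.uniform(0.05, 0.20),
            self_consumption_energy=rng.uniform(50.0, 500.0),
            self_consumption_electricity=rng.uniform(5.0, 50.0),
        )

    area = rng.uniform(100.0, 1000.0)
    manured = area * rng.uniform(0.2, 0.8)
    farm = FarmSpec(
        n_farms=int(rng.integers(1, 6)),
        area_per_farm=area,
        nutrient_requirement={
            "N": rng.uniform(60.0, 160.0),
            "P": rng.uniform(20.0, 60.0),
            "K": rng.uniform(40.0, 120.0),
        },
        manure_per_farm=rng.uniform(5000.0, 20000.0),
        manure_application_rate=rng.uniform(20.0, 40.0),
        mixed_fertiliser_rate_manured=rng.uniform(300.0, 600.0),
        mixed_fertiliser_rate_mineral_only=rng.uniform(400.0, 700.0),
        manured_area=manured,
        mineral_only_area=area - manured,
    )

    prices = {
        "fish_co_stream": Price(value=rng.uniform(50.0, 300.0), basis="per_t"),
        "steam": Price(value=rng.uniform(10.0, 40.0), basis="per_t"),
        "electricity": Price(value=rng.uniform(50.0, 200.0), basis="per_MWh"),
        "mineral_fertilisers": Price(value=rng.uniform(200.0, 800.0), basis="per_t"),
    }
    # price every sold product; the residue stays inside the battery limits
    for name in product_names:
        prices[name] = Price(value=rng.uniform(*spec.price_range), basis="per_t")

    n_plants = farm.n_farms if spec.has_biogas else 0
    capex = CapexSpec(
        processing_investment=rng.uniform(*spec.capex_range),
        biogas_investment_per_farm=rng.uniform(*spec.capex_range) * 0.3,
        n_biogas_plants=n_plants,
    )
    opex = OpexFactors(
        operators=int(rng.integers(1, 7)),
        salary=rng.uniform(40_000.0, 80_000.0),
        indirect_labour_frac=rng.uniform(0.0, 0.5),
        maintenance_frac=rng.uniform(0.005, 0.05),
        depreciation_time=rng.uniform(10.0, 20.0),
        other_indirect_frac=rng.uniform(0.005, 0.03),
        logistics_rate=rng.uniform(0.05, 0.2),
        distance_km=rng.uniform(10.0, 200.0),
    )

    demand_t = farm.n_farms * (
        farm.manured_area * farm.mixed_fertiliser_rate_manured
        + farm.mineral_only_area * farm.mixed_fertiliser_rate_mineral_only
    ) / KG_PER_T
    offset = rng.uniform(0.0, 0.5 * demand_t) if spec.has_residue else 0.0

    return ScenarioConfig(
        concept_id=f"synthetic-{spec.seed}",
        capacity=float(rng.uniform(*spec.capacity_range)),
        operating_hours=rng.uniform(2000.0, 8000.0),
        balance=balance,
        biogas=biogas,
        farm=farm,
        prices=PriceTable(prices=prices),
        capex=capex,
        opex=opex,
        transport_distance_km=opex.distance_km,
        digestate_fertiliser_offset_t=offset,
    )
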