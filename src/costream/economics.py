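"""Annual cost/revenue statements, fertiliser balance, profit and ROI.

The cost side prices every purchased input stream (raw materials and
utilities), adds labour, residue logistics, maintenance, straight-line
depreciation, other indirect costs and purchased mineral fertilisers.  The
revenue side prices every sold product, grouped into oil / protein / meal
lines, plus gross CHP electricity sold to the network.  Profitability is
summarised as

    ROI = annual net profit / investment costs

with no discounting, tax or financing structure: the published evaluation
reports a single representative operating year.

Line arithmetic is carried unrounded; :func:`round_millions` belongs to the
reporting layer only.
"""

from __future__ import annotations

import warnings
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Optional

import pandas as pd
from pydantic import BaseModel, Field

from .core import (
    AnnualFlows,
    CapexSpec,
    FarmSpec,
    KG_PER_T,
    OpexFactors,
    PriceTable,
    ScenarioConfig,
    annualize,
)

__all__ = [
    "UTILITY_STREAMS",
    "PRODUCT_GROUPS",
    "UNSOLD_OUTPUTS",
    "COST_LINES",
    "REVENUE_LINES",
    "EconomicStatement",
    "FertiliserBalance",
    "cost_statement",
    "revenue_statement",
    "fertiliser_balance",
    "profit_and_roi",
    "evaluate",
    "round_millions",
    "statements_to_frame",
]

#: Input streams billed on the utilities line; everything else purchased is
#: a raw material.
UTILITY_STREAMS = frozenset({"steam", "electricity", "water"})

#: Output streams that stay inside the battery limits instead of being sold.
UNSOLD_OUTPUTS = frozenset({"residue"})

#: Revenue grouping of the product slate; unknown products fall into "other".
PRODUCT_GROUPS: Mapping[str, str] = {
    "premium_oil": "oil",
    "oil": "oil",
    "fish_protein_concentrate": "protein",
    "fish_protein_hydrolysate": "protein",
    "meal": "meal",
    "silage": "meal",
}

COST_LINES = (
    "raw_materials",
    "utilities",
    "labour",
    "logistics",
    "maintenance",
    "depreciation",
    "other_indirect",
    "mineral_fertilisers",
)
REVENUE_LINES = ("oil", "protein", "meal", "energy", "other")


class FertiliserBalance(BaseModel):
    """Annual mineral-fertiliser purchase after digestate substitution."""

    demand_t: float = Field(ge=0.0, description="t/a before substitution")
    offset_t: float = Field(ge=0.0, description="t/a displaced by digestate")
    purchased_t: float = Field(ge=0.0, description="t/a bought")
    cost: float = Field(ge=0.0, description="USD/a")

    model_config = {"frozen": True}


class EconomicStatement(BaseModel):
    """Annual economic statement of one scenario (all lines USD/a)."""

    concept_id: str
    costs: dict[str, float]
    revenues: dict[str, float]
    total_investment: float = Field(ge=0.0)
    profit: float
    #: profit / total investment; None when the investment is zero.
    roi: Optional[float]

    model_config = {"frozen": True}

    @property
    def cost_total(self) -> float:
        return sum(self.costs.values())

    @property
    def revenue_total(self) -> float:
        return sum(self.revenues.values())


def fertiliser_balance(
    farm: FarmSpec,
    digestate_offset_t: float,
    prices: PriceTable,
) -> FertiliserBalance:
    """Mineral fertiliser needed by the farms after digestate credit.

    Demand sums, over all farms, the mixed-fertiliser application on the
    manured area and on the mineral-only area.  The digestate offset is the
    purchased tonnage it displaces; an offset exceeding the demand is
    clamped to zero residual purchase with a warning.
    """
    demand_kg = farm.n_farms * (
        farm.manured_area * farm.mixed_fertiliser_rate_manured
        + farm.mineral_only_area * farm.mixed_fertiliser_rate_mineral_only
    )
    demand_t = demand_kg / KG_PER_T
    if digestate_offset_t > demand_t:
        warnings.warn(
            f"digestate offset {digestate_offset_t:.1f} t/a exceeds farm demand "
            f"{demand_t:.1f} t/a; residual purchase clamped to zero",
            stacklevel=2,
        )
    purchased = max(demand_t - digestate_offset_t, 0.0)
    cost = purchased * prices.value("mineral_fertilisers") if purchased > 0 else 0.0
    return FertiliserBalance(
        demand_t=demand_t,
        offset_t=min(digestate_offset_t, demand_t),
        purchased_t=purchased,
        cost=cost,
    )


def cost_statement(
    scenario: ScenarioConfig,
    prices: Optional[PriceTable] = None,
    capex: Optional[CapexSpec] = None,
    opex: Optional[OpexFactors] = None,
    flows: Optional[AnnualFlows] = None,
) -> dict[str, float]:
    """Annual cost lines in USD/a.

    The fish co-stream itself is a purchased raw material.  Logistics covers
    hauling the residue stream to the farm-scale digesters; concepts that
    leave no residue ship nothing.  Maintenance, depreciation and other
    indirect costs are factors on the total investment.
    """
    prices = prices if prices is not None else scenario.prices
    capex = capex if capex is not None else scenario.capex
    opex = opex if opex is not None else scenario.opex
    flows = flows if flows is not None else annualize(scenario.balance, scenario.capacity)

    raw = 0.0
    util = 0.0
    for f in flows:
        if f.role != "input":
            continue
        value = prices.annual_value(f.name, f.annual, f.unit)
        if f.name in UTILITY_STREAMS:
            util += value
        else:
            raw += value

    residue_t = flows.annual("residue", "output")
    investment = capex.total_investment
    fert = fertiliser_balance(
        scenario.farm, scenario.digestate_fertiliser_offset_t, prices
    )
    return {
        "raw_materials": raw,
        "utilities": util,
        "labour": opex.operators * opex.salary * (1.0 + opex.indirect_labour_frac),
        "logistics": residue_t * opex.distance_km * opex.logistics_rate,
        "maintenance": opex.maintenance_frac * investment,
        "depreciation": investment / opex.depreciation_time,
        "other_indirect": opex.other_indirect_frac * investment,
        "mineral_fertilisers": fert.cost,
    }


def revenue_statement(
    scenario: ScenarioConfig,
    prices: Optional[PriceTable] = None,
    flows: Optional[AnnualFlows] = None,
) -> dict[str, float]:
    """Annual revenue lines in USD/a, grouped oil / protein / meal / energy.

    The energy line sells the gross CHP electricity generation at the grid
    price; heat is used internally and not sold.
    """
    prices = prices if prices is not None else scenario.prices
    flows = flows if flows is not None else annualize(scenario.balance, scenario.capacity)

    lines = {name: 0.0 for name in REVENUE_LINES}
    for f in flows:
        if f.role != "output" or f.name in UNSOLD_OUTPUTS:
            continue
        group = PRODUCT_GROUPS.get(f.name, "other")
        lines[group] += prices.annual_value(f.name, f.annual, f.unit)

    if scenario.biogas is not None:
        gross_kwh = scenario.biogas.electricity_output * scenario.capacity
        lines["energy"] += prices.annual_value(
            "electricity", gross_kwh, "kWh/t_RM"
        )
    return lines


def profit_and_roi(
    statement: EconomicStatement, capex: Optional[CapexSpec] = None
) -> tuple[float, Optional[float]]:
    """Profit = revenues - costs; ROI = profit / total investment.

    Computed on unrounded line values; a zero investment yields ROI None.
    """
    investment = (
        capex.total_investment if capex is not None else statement.total_investment
    )
    profit = statement.revenue_total - statement.cost_total
    roi = profit / investment if investment > 0 else None
    return profit, roi


def evaluate(
    scenario: ScenarioConfig,
    prices: Optional[PriceTable] = None,
    flows: Optional[AnnualFlows] = None,
) -> EconomicStatement:
    """Full statement for one scenario, optionally under replaced prices.

    ``flows`` may be passed to avoid recomputing the (price-independent)
    annual flows when the same scenario is evaluated many times, as in the
    Monte Carlo loop.
    """
    if flows is None:
        flows = annualize(scenario.balance, scenario.capacity)
    costs = cost_statement(scenario, prices=prices, flows=flows)
    revenues = revenue_statement(scenario, prices=prices, flows=flows)
    investment = scenario.capex.total_investment
    profit = sum(revenues.values()) - sum(costs.values())
    roi = profit / investment if investment > 0 else None
    return EconomicStatement(
        concept_id=scenario.concept_id,
        costs=costs,
        revenues=revenues,
        total_investment=investment,
        profit=profit,
        roi=roi,
    )


def round_millions(value: float, decimals: int = 1) -> float:
    """Round a USD value to 10^6 USD at the given decimals, half away from zero."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value / 1e6)).quantize(q, rounding=ROUND_HALF_UP))


def statements_to_frame(statements: list[EconomicStatement]) -> pd.DataFrame:
    """Line items as rows, one column per concept (USD/a, unrounded)."""
    cols = {}
    for st in statements:
        col = {f"cost:{k}": v for k, v in st.costs.items()}
        col.update({f"revenue:{k}": v for k, v in st.revenues.items()})
        col["cost_total"] = st.cost_total
        col["revenue_total"] = st.revenue_total
        col["profit"] = st.profit
        col["roi"] = st.roi if st.roi is not None else float("nan")
        cols[st.concept_id] = col
    return pd.DataFrame(cols)
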