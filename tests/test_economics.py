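"""Cost/revenue statements, fertiliser balance, profit and ROI."""

import pytest
from hypothesis import given, strategies as st

from costream import (
    MissingPriceError,
    Price,
    PriceTable,
    annualize,
    cost_statement,
    evaluate,
    fertiliser_balance,
    load_concept,
    profit_and_roi,
    revenue_statement,
    round_millions,
)
from costream.core import CapexSpec
from costream.economics import UTILITY_STREAMS, PRODUCT_GROUPS
from costream.synthetic import SyntheticScenarioSpec, generate_scenario


def _brute_force_statement(scenario):
    """Independent spreadsheet-style recomputation of every line."""
    cap = scenario.capacity
    prices = scenario.prices
    raw = util = 0.0
    for s in scenario.balance.streams:
        if s.role != "input":
            continue
        if s.unit == "kg/t_RM":
            value = s.quantity / 1000.0 * cap
        else:
            value = s.quantity * cap
        p = prices.get(s.name)
        if p.basis == "per_kg":
            usd = value * 1000.0 * p.value
        elif p.basis == "per_MWh":
            usd = value / 1000.0 * p.value
        else:
            usd = value * p.value
        if s.name in UTILITY_STREAMS:
            util += usd
        else:
            raw += usd
    opex, capex, farm = scenario.opex, scenario.capex, scenario.farm
    inv = capex.processing_investment + capex.n_biogas_plants * capex.biogas_investment_per_farm
    residue_t = 0.0
    res = scenario.balance.get("residue", "output")
    if res is not None:
        residue_t = res.quantity / 1000.0 * cap
    demand_t = farm.n_farms * (
        farm.manured_area * farm.mixed_fertiliser_rate_manured
        + farm.mineral_only_area * farm.mixed_fertiliser_rate_mineral_only
    ) / 1000.0
    purchased = max(demand_t - scenario.digestate_fertiliser_offset_t, 0.0)
    costs = {
        "raw_materials": raw,
        "utilities": util,
        "labour": opex.operators * opex.salary * (1 + opex.indirect_labour_frac),
        "logistics": residue_t * opex.distance_km * opex.logistics_rate,
        "maintenance": opex.maintenance_frac * inv,
        "depreciation": inv / opex.depreciation_time,
        "other_indirect": opex.other_indirect_frac * inv,
        "mineral_fertilisers": purchased * prices.value("mineral_fertilisers"),
    }
    revenue = 0.0
    for s in scenario.balance.streams:
        if s.role == "output" and s.name != "residue":
            revenue += s.quantity / 1000.0 * cap * prices.value(s.name)
    if scenario.biogas is not None:
        revenue += scenario.biogas.electricity_output * cap / 1000.0 * prices.value(
            "electricity"
        )
    return costs, revenue


class TestCostLines:
    def test_raw_materials_full_codigestion(self, statements):
        assert statements["I"].costs["raw_materials"] == pytest.approx(1.2e6)

    def test_depreciation_straight_line(self, statements):
        assert statements["I"].costs["depreciation"] == pytest.approx(10.4e6 / 15)
        assert round_millions(statements["I"].costs["depreciation"]) == 0.7

    def test_utilities_require_tonne_basis_steam(self, statements):
        # 0.7 t steam x 10,000 t x 20 USD/t + 40 kWh x 10,000 t at 100 USD/MWh
        assert statements["III"].costs["utilities"] == pytest.approx(180_000.0)

    def test_logistics_scales_with_residue(self, statements):
        assert statements["I"].costs["logistics"] == pytest.approx(100_000.0)
        assert statements["IV"].costs["logistics"] == pytest.approx(13_000.0)
        assert statements["II"].costs["logistics"] == 0.0

    def test_zero_capacity_leaves_only_fixed_lines(self):
        sc = load_concept("III").model_copy(update={"capacity": 0.0})
        costs = cost_statement(sc)
        assert costs["raw_materials"] == costs["utilities"] == costs["logistics"] == 0.0
        for line in ("labour", "maintenance", "depreciation", "other_indirect"):
            assert costs[line] > 0.0

    def test_missing_price_named_error(self):
        sc = load_concept("II")
        bad = PriceTable(
            prices={k: v for k, v in sc.prices.prices.items() if k != "formic_acid"}
        )
        with pytest.raises(MissingPriceError, match="formic_acid"):
            cost_statement(sc, prices=bad)


class TestRevenueLines:
    def test_silage_revenue(self, statements):
        assert statements["II"].revenues["meal"] == pytest.approx(2.4e6)

    def test_two_stage_oil_line_groups_both_oils(self, statements):
        expected = (175 * 1350 + 46 * 1200) / 1000.0 * 10_000
        assert statements["IV"].revenues["oil"] == pytest.approx(expected)
        assert round_millions(statements["IV"].revenues["oil"]) == 2.9

    def test_energy_revenue_is_gross_chp_electricity(self, statements):
        assert statements["I"].revenues["energy"] == pytest.approx(1213 * 10_000 / 1000 * 100)
        assert statements["IV"].revenues["energy"] == pytest.approx(158_000.0)

    def test_concepts_without_products_sell_nothing_but_energy(self, statements):
        st_i = statements["I"]
        assert st_i.revenues["oil"] == st_i.revenues["protein"] == st_i.revenues["meal"] == 0.0

    def test_empty_product_slate(self):
        sc = load_concept("I")
        flows = annualize(sc.balance, 0.0)
        lines = revenue_statement(sc.model_copy(update={"capacity": 0.0}), flows=flows)
        assert all(v == 0.0 for v in lines.values())


class TestFertiliserBalance:
    def test_mineral_only_concepts(self, concepts):
        sc = concepts["II"]
        fb = fertiliser_balance(sc.farm, 0.0, sc.prices)
        assert fb.demand_t == pytest.approx(1201.6)
        assert fb.cost == pytest.approx(600_800.0)

    def test_digestate_covers_full_demand(self, statements):
        assert statements["I"].costs["mineral_fertilisers"] == 0.0

    def test_partial_digestate_offset(self, statements):
        assert statements["IV"].costs["mineral_fertilisers"] == pytest.approx(500_000.0)

    def test_zero_area_farm(self, concepts):
        farm = concepts["II"].farm.model_copy(
            update={"area_per_farm": 0.0, "manured_area": 0.0, "mineral_only_area": 0.0}
        )
        fb = fertiliser_balance(farm, 0.0, concepts["II"].prices)
        assert fb.cost == 0.0

    def test_excess_offset_clamped_with_warning(self, concepts):
        sc = concepts["II"]
        with pytest.warns(UserWarning, match="clamped"):
            fb = fertiliser_balance(sc.farm, 1e6, sc.prices)
        assert fb.purchased_t == 0.0 and fb.cost == 0.0


class TestProfitAndRoi:
    def test_full_codigestion_runs_at_loss(self, statements):
        st_ = statements["I"]
        assert round_millions(st_.profit) == -1.3
        assert round(st_.roi * 100) == -13

    def test_thermal_concept_roi(self, statements):
        assert round(statements["III"].roi * 100) == 42

    def test_zero_investment_roi_undefined(self, statements):
        profit, roi = profit_and_roi(
            statements["II"],
            CapexSpec(processing_investment=0.0),
        )
        assert roi is None

    def test_zero_profit_zero_roi(self, statements):
        st_ = statements["II"]
        balanced = st_.model_copy(update={"revenues": dict(st_.costs)})
        profit, roi = profit_and_roi(balanced)
        assert profit == pytest.approx(0.0)
        assert roi == pytest.approx(0.0)


class TestStatementProperties:
    @pytest.mark.parametrize("seed", range(25))
    @pytest.mark.parametrize("residue", [True, False])
    def test_identity_and_bruteforce_oracle(self, seed, residue):
        sc = generate_scenario(
            SyntheticScenarioSpec(seed=seed, has_residue=residue, has_biogas=residue)
        )
        st_ = evaluate(sc)
        assert st_.profit + st_.cost_total == pytest.approx(st_.revenue_total, rel=1e-12)
        costs, revenue = _brute_force_statement(sc)
        for line, value in costs.items():
            assert st_.costs[line] == pytest.approx(value, rel=1e-9, abs=1e-6), line
        assert st_.revenue_total == pytest.approx(revenue, rel=1e-9)

    def test_statement_identity_on_fixtures(self, statements):
        for st_ in statements.values():
            assert st_.profit + st_.cost_total == pytest.approx(st_.revenue_total)

    @given(k=st.floats(min_value=0.1, max_value=10.0, allow_nan=False))
    def test_roi_invariant_under_uniform_price_and_capex_scaling(self, k):
        sc = load_concept("III")
        scaled_prices = PriceTable(
            prices={n: Price(value=p.value * k, basis=p.basis) for n, p in sc.prices.prices.items()}
        )
        scaled = sc.model_copy(
            update={
                "prices": scaled_prices,
                "capex": sc.capex.model_copy(
                    update={"processing_investment": sc.capex.processing_investment * k}
                ),
                "opex": sc.opex.model_copy(
                    update={
                        "salary": sc.opex.salary * k,
                        "logistics_rate": sc.opex.logistics_rate * k,
                    }
                ),
            }
        )
        assert evaluate(scaled).roi == pytest.approx(evaluate(sc).roi, rel=1e-9)

    def test_scaling_revenues_raises_profit_monotonically(self, concepts):
        sc = concepts["III"]
        sold = [s.name for s in sc.balance.outputs() if s.name != "residue"]
        profits = []
        for k in (1.0, 1.1, 1.3):
            prices = sc.prices.replace(
                {n: sc.prices.value(n) * k for n in sold}
            )
            profits.append(evaluate(sc, prices=prices).profit)
        assert profits[0] < profits[1] < profits[2]
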