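"""Price-uncertainty analysis: Monte Carlo profit distribution and
one-at-a-time sensitivity ranking.

Five market factors — raw material, energy, fish oil, fish protein and fish
meal — are varied by a multiplicative draw in [1-v, 1+v] (default v = 0.20)
around the base price table.  Each factor drives one or more price entries
(e.g. the "fish oil" factor moves both the premium-oil and the regular-oil
price together), and correlated prices (mineral fertilisers and formic acid
tracking the energy price) reuse the driver's multiplier, i.e. perfect rank
correlation.

Because the statement is linear in every price, the profit distribution is
a shifted linear combination of the factor draws; the closed-form mean and
standard deviation are used as test oracles, not by this module.

Reproducibility: draws are generated per iteration from a generator seeded
with (seed, iteration index), and factors are consumed in name-sorted
order, so results are independent of chunking and stable across platforms.
"""

from __future__ import annotations

from typing import Literal, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .core import PriceTable, ScenarioConfig
from .economics import EconomicStatement, evaluate
from .core import annualize

__all__ = [
    "DEFAULT_FACTOR_PRICE_MAP",
    "DEFAULT_CORRELATION_GROUPS",
    "UncertaintyConfig",
    "ProfitDistribution",
    "FactorSwing",
    "SensitivityResult",
    "sample_prices",
    "run_monte_carlo",
    "sensitivity_ranking",
]

#: Which price-table entries each market factor drives.  "fish protein"
#: covers the protein concentrate and the hydrolysate, "fish meal" covers
#: dried meal and silage — whichever the concept actually sells.
DEFAULT_FACTOR_PRICE_MAP: Mapping[str, tuple[str, ...]] = {
    "raw_material": ("fish_co_stream",),
    "energy": ("electricity",),
    "fish_oil": ("premium_oil", "oil"),
    "fish_protein": ("fish_protein_concentrate", "fish_protein_hydrolysate"),
    "fish_meal": ("meal", "silage"),
}

#: Prices that move with another factor's multiplier (price name -> factor).
DEFAULT_CORRELATION_GROUPS: Mapping[str, str] = {
    "mineral_fertilisers": "energy",
    "formic_acid": "energy",
}


class UncertaintyConfig(BaseModel):
    """Configuration of the price-uncertainty study."""

    varied_factors: tuple[str, ...] = tuple(sorted(DEFAULT_FACTOR_PRICE_MAP))
    variation: float = Field(ge=0.0, lt=1.0, default=0.20)
    distribution: Literal["uniform", "triangular"] = "uniform"
    iterations: int = Field(ge=1, default=10_000)
    seed: int = 0
    factor_price_map: dict[str, tuple[str, ...]] = Field(
        default_factory=lambda: {k: tuple(v) for k, v in DEFAULT_FACTOR_PRICE_MAP.items()}
    )
    correlation_groups: dict[str, str] = Field(
        default_factory=lambda: dict(DEFAULT_CORRELATION_GROUPS)
    )

    model_config = {"frozen": True}

    @model_validator(mode="after")
    def _factors_known(self) -> "UncertaintyConfig":
        for f in self.varied_factors:
            if f not in self.factor_price_map:
                raise KeyError(
                    f"unknown factor {f!r}; known factors: "
                    f"{sorted(self.factor_price_map)}"
                )
        for price, driver in self.correlation_groups.items():
            if driver not in self.factor_price_map:
                raise KeyError(f"correlation driver {driver!r} is not a known factor")
        return self


def _draw_multipliers(cfg: UncertaintyConfig, draw_index: int) -> dict[str, float]:
    """One multiplier per varied factor, consumed in name-sorted order."""
    rng = np.random.default_rng([cfg.seed, draw_index])
    v = cfg.variation
    out: dict[str, float] = {}
    for factor in sorted(cfg.varied_factors):
        if v == 0.0:
            out[factor] = 1.0
        elif cfg.distribution == "uniform":
            out[factor] = rng.uniform(1.0 - v, 1.0 + v)
        else:
            out[factor] = rng.triangular(1.0 - v, 1.0, 1.0 + v)
    return out


def _apply_multipliers(
    base: PriceTable, cfg: UncertaintyConfig, multipliers: Mapping[str, float]
) -> PriceTable:
    new_values: dict[str, float] = {}
    for factor, m in multipliers.items():
        for price_name in cfg.factor_price_map[factor]:
            if price_name in base:
                new_values[price_name] = base.value(price_name) * m
    for price_name, driver in cfg.correlation_groups.items():
        if driver in multipliers and price_name in base:
            new_values[price_name] = base.value(price_name) * multipliers[driver]
    return base.replace(new_values)


def sample_prices(
    base: PriceTable, cfg: UncertaintyConfig, draw_index: int = 0
) -> PriceTable:
    """One sampled price table; prices outside the varied factors untouched."""
    return _apply_multipliers(base, cfg, _draw_multipliers(cfg, draw_index))


class ProfitDistribution(BaseModel):
    """Monte Carlo profit draws with summary statistics (USD/a)."""

    samples: tuple[float, ...]
    baseline: float
    mean: float
    sd: float
    q05: float
    q50: float
    q95: float

    model_config = {"frozen": True}

    def to_summary(self) -> dict[str, float]:
        return {
            "baseline": self.baseline,
            "mean": self.mean,
            "sd": self.sd,
            "q05": self.q05,
            "q50": self.q50,
            "q95": self.q95,
        }


def run_monte_carlo(scenario: ScenarioConfig, cfg: UncertaintyConfig) -> ProfitDistribution:
    """Re-evaluate the full economic statement under sampled prices.

    The baseline is the deterministic statement at the base prices; at zero
    variation every sample collapses onto it exactly.
    """
    flows = annualize(scenario.balance, scenario.capacity)
    baseline = evaluate(scenario, flows=flows).profit
    samples = np.empty(cfg.iterations)
    for i in range(cfg.iterations):
        prices = sample_prices(scenario.prices, cfg, draw_index=i)
        samples[i] = evaluate(scenario, prices=prices, flows=flows).profit
    q05, q50, q95 = np.quantile(samples, [0.05, 0.50, 0.95])
    return ProfitDistribution(
        samples=tuple(samples.tolist()),
        baseline=baseline,
        mean=float(samples.mean()),
        sd=float(samples.std(ddof=1)) if cfg.iterations > 1 else 0.0,
        q05=float(q05),
        q50=float(q50),
        q95=float(q95),
    )


class FactorSwing(BaseModel):
    """Profit at the low and high bound of one factor, others at baseline."""

    factor: str
    profit_low: float
    profit_high: float

    model_config = {"frozen": True}

    @property
    def swing(self) -> float:
        return abs(self.profit_high - self.profit_low)


class SensitivityResult(BaseModel):
    """One-at-a-time tornado of the varied factors."""

    baseline: float
    swings: tuple[FactorSwing, ...]

    model_config = {"frozen": True}

    @property
    def ranking(self) -> tuple[str, ...]:
        """Factors ordered by decreasing swing; ties broken by name."""
        return tuple(
            s.factor for s in sorted(self.swings, key=lambda s: (-s.swing, s.factor))
        )

    def to_frame(self) -> pd.DataFrame:
        order = {f: r + 1 for r, f in enumerate(self.ranking)}
        return pd.DataFrame(
            [
                {
                    "factor": s.factor,
                    "profit_low": s.profit_low,
                    "profit_high": s.profit_high,
                    "swing": s.swing,
                    "rank": order[s.factor],
                }
                for s in self.swings
            ]
        ).sort_values("rank", ignore_index=True)


def sensitivity_ranking(scenario: ScenarioConfig, cfg: UncertaintyConfig) -> SensitivityResult:
    """Evaluate profit at the +/-v bound of each factor, others at baseline."""
    flows = annualize(scenario.balance, scenario.capacity)
    baseline = evaluate(scenario, flows=flows).profit
    swings = []
    for factor in sorted(cfg.varied_factors):
        lo = _apply_multipliers(scenario.prices, cfg, {factor: 1.0 - cfg.variation})
        hi = _apply_multipliers(scenario.prices, cfg, {factor: 1.0 + cfg.variation})
        swings.append(
            FactorSwing(
                factor=factor,
                profit_low=evaluate(scenario, prices=lo, flows=flows).profit,
                profit_high=evaluate(scenario, prices=hi, flows=flows).profit,
            )
        )
    return SensitivityResult(baseline=baseline, swings=tuple(swings))
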