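# Methods

## Scope and model form

`costream` evaluates four zero-waste processing routes for salmon filleting
co-streams within fixed battery limits: one processing plant
(10,000 t_RM/a, ~3000 h/a one-shift operation for the product concepts)
plus four receiving farms (600 ha barley and 600 milking cows each,
12,000 t/a manure per farm, 100 km from the plant). Each concept is a fixed
per-tonne coefficient table (`ProcessBalance`), not a thermodynamic or
kinetic model: all downstream quantities are linear in plant capacity.
This is the appropriate fidelity for early-stage concept screening, where
the published balances are themselves fixed per-tonne figures.

Out of scope by design: life-cycle/GHG accounting, digester biochemical
kinetics, logistics route optimisation, crop-yield response to
fertilisation, cash-flow discounting (no NPV/IRR — profitability is a
single representative year and ROI).

## Units and conversions

All per-tonne coefficients are keyed to t_RM = one tonne of co-stream
entering the plant. The closed unit set is {kg/t_RM, t/t_RM, kWh/t_RM,
m³/t_RM}; conversions happen only at computation boundaries (kg→t at 10⁻³,
kWh→MJ at 3.6). Steam coefficients are carried in t/t_RM: the kg/t_RM
reading fails to reproduce the utilities cost line by two orders of
magnitude, so the tonne basis is the only consistent interpretation of the
balance table (the unit is configurable on the stream). Currency is USD
throughout; the EUR↔USD factor 1.1 is retained as a display constant only.

## Biogas / CHP plant

The co-digestion plant is a linear operating-point model
(`BiogasPlantSpec`): wet single-stage mesophilic digestion (38 °C, OLR
2 kg VS/m³/d, 12.1 wt.% TS in the mixed feed, 2300 m³ digester) of one part
fish residue to five parts cattle manure. Biogas = feed mass × 88 m³/t of
mixture at 65 v.% CH₄; CHP heat, electricity and digestate scale linearly
with residue throughput relative to the basis (concept I: 1 t residue/t_RM
→ 1562 kWh heat, 1213 kWh electricity, 5168 kg digestate; concept IV:
0.13 t residue/t_RM → 203 / 158 kWh, 662 kg). No efficiency chain is
modelled — the operating point already embodies it. A validity bound is
enforced at construction: CHP heat + electricity (MJ) may never exceed the
chemical energy of the methane produced at LHV 35.9 MJ/m³.

Feeding the plant off its design ratio warns rather than fails: the yield
figure was measured at 1:5 and linear extrapolation across ratios is not
claimed.

## Energy ledgers and reconciliation entries

Per-operation direct/indirect energy coefficients (field work, spreading,
plant operation) are not published item-by-item; only aggregates are:
processing 82 / 326 / 377 / 678 MJ/t_RM for concepts I–IV, digester
self-consumption 2196 / 293 MJ/t_RM (I / IV), transport 82.1 MJ/t_RM, total
input 2548 MJ/t_RM (I) and input/output ratio 1.0 (IV). The shipped
ledgers carry those aggregates as entries and close each biogas concept
with one `digestate field operations` entry flagged `reconciliation: true`
(I: 187.9 MJ/t_RM to reach the published 2548; IV: 246.5 MJ/t_RM to reach
ratio 1.0, for which no total input is published). The direct/indirect
split of reconciliation entries is an assumption (80/20, fuel-dominated
field work); only their totals are constrained, and nothing downstream
depends on the split.

Similarly, published useful electricity (1042 / −41 / −51 / 66 kWh/t_RM)
exceeds the itemised process consumption by a consistent 11 kWh/t_RM in
concepts I–III; the consumer lists therefore include a `farm-side use`
entry flagged as reconciliation, and concept IV closes with 60 (process) +
21 (digester) + 11 (farm-side). The discrepancy is surfaced in the
fixtures, not silently absorbed.

## Economic statement

Cost lines: purchased inputs split into raw materials vs utilities (steam,
electricity, water); labour = operators × 65,000 USD/a × 1.4 (40% indirect
on top); logistics = residue tonnage × 100 km × 0.1 USD/t/km (only the
residue leaves the plant by lorry); maintenance 2.5% and other indirect 1%
of total investment per year; straight-line depreciation over 15 a with
zero salvage; mineral fertilisers from the farm balance below. Concepts
buy only what their balance lists — concept I has no utility inputs at
all (plant self-supply).

Revenue lines group the product slate into oil (premium + regular),
protein (concentrate or hydrolysate), meal (dried meal or silage) and
energy. The energy line sells **gross** CHP electricity at 100 USD/MWh:
only the gross figure reproduces the published revenue line; heat is used
internally and unsold. Parasitic electricity appears on the cost side via
the energy ledger/utilities, not netted out of revenue.

Farm fertiliser balance: without digestate each farm applies 484 kg/ha of
mixed mineral fertiliser on its 400 manured ha and 534 kg/ha on its 200
mineral-only ha → 1201.6 t/a demand over four farms (0.6 × 10⁶ USD/a at
500 USD/t). Digestate displaces purchased tonnage via a single offset
parameter: the full demand in concept I, zero in II/III, and 201.6 t/a in
concept IV. The IV offset is calibrated to the published 0.5 × 10⁶ USD/a
fertiliser cost because no nutrient-substitution formula is published; the
nutrient analyses of both feedstocks are shipped should a mass-balance
offset be modelled later. Offsets exceeding demand clamp to zero purchase
with a warning.

All line arithmetic is exact and unrounded; rounding to the printed
precision (0.1 × 10⁶ USD, whole %) happens only in the reporting layer,
half away from zero.

## Known deviations in the reference tables

Two revenue lines in the reference results do not follow from the
reference's own inputs: concept III oil (printed 2.3 × 10⁶; 187 kg/t ×
10,000 t × 1200 USD/t = 2.24 × 10⁶) and concept IV protein (printed
6.6 × 10⁶; computed 6.67 × 10⁶); concept III meal behaves the same way
(printed 2.2 × 10⁶; computed 2.13 × 10⁶). These propagate into the
concept III revenue total and the concept IV cost total, profit and ROI
(computed 52% vs printed 51%). The comparison report flags exactly these
seven cells as `known-deviation`; all other 78 table cells, including
profit and ROI of concepts I–III, reproduce at printed precision.

## Uncertainty analysis

Factor distribution is not published beyond the ±20% bounds, so the
default is uniform on [0.8, 1.2] — the stated bounds with no extra
assumptions — with triangular as an option. Correlation ("mineral
fertiliser and formic acid prices follow energy") is implemented as reuse
of the driver's multiplier, i.e. perfect rank correlation, the minimal
reading. The "fish protein" factor moves both protein-product prices and
"fish meal" both meal-type prices, so each concept responds through the
product it actually sells.

Draws use one NumPy generator seeded per iteration with (seed, iteration
index) and are consumed in factor-name-sorted order, making results
bit-reproducible, independent of chunking, and stable across platforms.
Default 10,000 iterations (≈1 s). Because the statement is linear in all
prices, the profit distribution has closed-form mean (= baseline) and
standard deviation; the test suite uses these as independent oracles, and
the one-at-a-time swing must equal |∂profit/∂multiplier| × 2v to machine
precision. Whether the published ranking came from joint sampling or
one-at-a-time perturbation is ambiguous; both modes are provided (`mc
--mode joint|oat`) and both reproduce the published qualitative ranking
(hydrolysate price dominant in IV; oil and meal above raw material in III;
energy ≈ raw material in I).

## Synthetic scenarios

`costream.synthetic` generates random scenarios with the same structural
shape as the study concepts: a 1000 kg/t_RM co-stream input, a Dirichlet
product slate whose material closure is ≤ 1 by construction, optional
utilities, an optional residue→co-digestion branch whose CHP output is
drawn below the methane LHV bound, and full farm/price/capex/opex
configuration. They emulate the accounting structure of real scenarios,
not their calibration — coefficients, prices and investments are drawn
from broad plausible ranges. Passing the property suite on them
demonstrates that the accounting identities (statement balance, mass
closure, energy identity, linearity, ROI homogeneity) hold over a wide
family, not that any particular real process is predicted.

## Numerical choices and degenerate inputs

* Zero capacity is representable: all variable lines vanish, fixed lines
  remain.
* Zero energy input reports the input/output ratio as undefined (`None`)
  rather than infinity; zero investment likewise for ROI.
* Sensitivity ties rank by factor name (deterministic tornado order).
* Comparison tolerance against printed values is half a unit in the last
  printed digit per cell (0.05 × 10⁶ USD at one decimal, 0.005 at two),
  0.5 percentage points for ROI, 0.5% relative for the MJ-scale energy
  aggregates, and half a decimal for the energy ratio.
* Problem sizes in the shipped checks: the four reference concepts at
  10,000 t_RM/a, 10,000 Monte Carlo iterations, 100 synthetic seeds for
  the property sweeps.

## Limitations

Fixed coefficients mean no response to feedstock quality, scale, or
operating policy; prices are static within a run except for the sampled
factors; the digestate fertiliser credit is a calibrated scalar, not a
nutrient balance; transport energy/cost uses a single lane and mode. The
two reconciliation mechanisms above are honest placeholders for
unpublished coefficients and should be replaced if itemised data become
available.
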