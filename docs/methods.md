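# Methods

`fvgap` projects the gap between fruit-and-vegetable (F&V) supply and
recommended consumption for a world of countries, using a simplified
partial-equilibrium multimarket model driven by SSP-style socioeconomic
scenarios, and classifies the public policies available to close that gap.
Because the real study inputs (FAO commodity balance sheets, UN population
pyramids, SSP country projections, the WCRF NOURISHING policy database) are
not redistributable, the pipeline runs end-to-end on a seeded synthetic
world with the same statistical structure. This note records the model, its
assumptions, the parameter choices, and what the synthetic setting does and
does not establish.

## The market model

For each country *c* and commodity *i* (three fruit commodities and one
vegetable commodity by default), demand and supply are constant-elasticity
(log-linear) in income and the world price *P* (index, base year = 1):

```
QD_food(c,i,t) = α(c,i) · N(c,t) · (y(c,t)/y0(c))^εy · P(i,t)^εp
QD_other(c,i,t) = λ(c,i) · QD_food(c,i,t)
QS(c,i,t)      = β(c,i) · P(i,t)^γ · Π_{s>t0} (1 + g(c,i,s))
```

* *N* population (persons), *y* per-capita income (USD/person/year).
* εy > 0 income elasticity, εp < 0 own-price elasticity, γ > 0 supply
  elasticity, *g* exogenous supply (productivity) growth per year.
* "Other demand" is an accounting category — processing and storage losses
  and non-food uses — carried as a calibrated proportional share λ of food
  demand rather than a behavioural equation. Post-harvest losses are
  treated as already netted out of the supply intercept.

Countries trade on a single integrated world market per commodity (no
bilateral flows, no trade margins; full price transmission). Each simulated
year the world price of each commodity is solved so that global supply
equals global demand. With εp < 0 < γ, world excess demand is strictly
decreasing in the price, so the clearing price is unique; the solver is
Brent-style bracketed root finding on an initial bracket [0.25, 4],
expanded geometrically to hard bounds [1e-3, 1e3] (a bracket failure raises
a convergence error naming the commodity and residual). Cross-price effects
are off by default; an optional cross-elasticity matrix switches the solver
to damped fixed-point iteration on the price vector (damping 0.5, at most
500 iterations, relative tolerance 1e-8).

Calibration is exact: with base-year drivers and P = 1 the model reproduces
the base balances identically (α = QD_food0/N0, λ = QD_other0/QD_food0,
β = QS0). Dynamics are recursive (annual), with exogenous drivers updated
each year and no intertemporal optimization. Years at or before the base
year replay the base-year balances at P = 1 — see "Limitations".

Per-capita availability, the quantity compared against dietary targets, is
`A(c,t) = Σ_i QD_food(c,i,t) · 1e6 / (N(c,t) · 365)` in g/person/day.
Availability is food supply at the household door, not intake.

## Recommended consumption targets

Two WHO-consistent targets are computed per country-year: a flat minimum of
400 g/person/day, and an age-specific set (330 g for ages 0–4, 480 g for
5–14, 600 g for 15+) collapsed to one national level by weighting with the
population pyramid, `R = Σ_a N_a r_a / Σ_a N_a`. R is scale-invariant in
the pyramid and bounded by [330, 600]; it rises as pyramids age. The three
bands are exactly the bands the recommendations distinguish, so band
populations (annual in the synthetic panels) are sufficient — no
within-band structure is needed. Alternative recommendation sets can be
injected; only the WHO sets ship as built-ins.

## Waste schemes and gap statistics

Household waste drives a wedge between availability and consumption:
`C = A·(1 − w)`. Four schemes are analysed: zero waste (the
availability-only view), FAO-style regional shares (anchored at 5% for
sub-Saharan Africa and 28% for the regions containing North America and
east Asia–Pacific; unanchored regions default to 15%), and uniform 15% and
33% futures. Pass/fail against either target is inclusive (C ≥ T passes).
Regional and global summaries are population-weighted means with counts of
passing countries and population living in them; both the minimum-target
and age-weighted-target columns are always emitted so either reading of
"sufficient" is reproducible. Within-country distribution is out of scope.

## Policy classification

NOURISHING-style policy records are filtered by case-insensitive substring
search for "fruit" or "vegetable" in the description (word-boundary
matching is a config option); records that only address general healthy
eating are thereby excluded, mirroring the stated inclusion rule. Records
registered to a regional bloc are expanded to all member countries (EU 28,
Caribbean Community 15, Pacific Island Nations and Territories 22). Each
NOURISHING category maps to exactly one rung of the Nuffield intervention
ladder (provide information → eliminate choice, seven rungs, fixed order);
the mapping is a versioned data file
(`src/fvgap/data/nourishing_to_nuffield.csv`) with three rows fixed by
published precedent — dietary guidelines → provide information,
store-location incentives → enable choice (the incentive targets the store
owner; the consumer's choice set merely widens), and F&V price-reduction
fiscal policies → guide choice with incentives — and the remaining rows as
editable implementation defaults. Tabulation counts distinct countries (not
records) per region × rung, reporting zero rows for unobserved rungs.

## The synthetic world generator

The generator emulates, per seed:

* **Countries and regions.** Default 20 countries over the seven regions
  used in global food-security reporting; income groups by tercile of
  base-year income.
* **Population.** Base-year (2010) totals drawn log-normal and rescaled to
  a 6.9 billion world total; scenario trajectories interpolate
  exponentially to 2050 country totals rescaled so the world hits each
  SSP anchor exactly (SSP1 8.5e9, SSP2 9.2e9, SSP3 9.96e9 persons).
  Age-band shares follow a piecewise-linear ageing path (younger pyramids
  historically, older by 2050); bands sum to totals exactly.
* **Income.** Base-year log-normal (median $8,000); future growth is
  convergence-flavoured (poorer countries grow faster) with a shared
  country shape scaled per scenario so the population-weighted world mean
  hits the GDP anchors ($34k / $25k / $18k). Sharing the shape across
  scenarios makes income paths scenario-ordered for every country.
* **Balances.** Base per-capita F&V availability log-normal (median
  250 g/day, σ = 0.4, mildly income-tilted, clipped to [60, 900]), split
  across commodities by a Dirichlet draw weighted toward vegetables;
  other-demand share uniform on [5%, 20%]; production drawn around total
  demand and closed at the world level by proportionally rescaling
  exporters' surpluses (the simplest closure preserving non-negativity).
* **Elasticities.** εy declines with income rank across [0.2, 1.0]
  (Engel-consistent) with commodity-level jitter; εp uniform on
  [−0.8, −0.2]; γ uniform on [0.2, 0.8]. These ranges guarantee γ − εp > 0
  and hence a unique equilibrium. Elasticities are constant over time.
* **Supply growth.** Uniform on [0.5%, 2%]/year, scaled by the scenario's
  productivity multiplier (1.2 / 1.0 / 0.8 for SSP1/2/3).
* **Policy records.** Jurisdictions drawn from bloc members (15% of
  records at bloc level), categories from the shipped taxonomy, and a
  configurable fraction (default 22%) of descriptions mentioning fruit or
  vegetables.

All randomness flows through one `numpy` generator seeded from the config;
identical configs give byte-identical CSV output.

## What the synthetic setting shows — and what it does not

Passing tests establish that the machinery is correct: exact calibration,
market clearing to 1e-6 relative, agreement with closed forms and
independent oracles (per-individual averaging for targets, bisection for
prices), the qualitative orderings (richer scenarios → higher availability;
more waste → fewer passing countries), and end-to-end determinism. They do
**not** reproduce published country-level numbers: those derive from the
full 158-country / 62-commodity modelling system with biophysical
sub-models and real databases. Magnitudes here depend on the synthetic
draws; only structure and direction carry over.

## Numerical choices and degenerate inputs

* Root finder tolerances: `xtol = 1e-13`, `rtol = 1e-12`; clearing
  residuals are reported per commodity-year in outputs and manifests.
* A commodity with zero world supply intercept and zero demand is marked
  inactive at price 1; zero supply with positive demand is a convergence
  error (no clearing price exists).
* λ is 0 when a country has neither food nor other demand; other demand
  without food demand is a calibration error.
* A zero-total pyramid is a degenerate-population error; ratio columns use
  +inf when the target is 0 (pass flags remain well-defined, and a 0/0 tie
  passes by the inclusive rule).
* Pipeline outputs round-trip losslessly: readers use `float_precision=
  "round_trip"`, and two runs with the same config/seed are byte-identical
  (manifests deliberately contain no timestamps).

## Problem sizes

The study configuration is 20 countries × 4 commodities over 1961–2050
(solved annually after 2010) under three scenarios — about 480 price
solves per full pipeline run, a few seconds on one core. The acceptance
script simulates four reporting years per scenario instead of the full
horizon; the analysis drivers run the full horizon.

## Limitations

* Historical years replay the base-year aggregate balances, so synthetic
  historical per-capita availability *falls* toward the base year as
  population grows — the generator does not backcast historical demand
  growth. Historical snapshots exercise the accounting, not history.
* One integrated world market abstracts from bilateral trade costs; no
  climate effects, no biophysical yield modelling, no welfare analysis,
  no within-country distribution, no calorie conversion.
* Elasticities are constant per country-commodity over time; real demand
  systems let income elasticities decline as countries grow richer.
* The taxonomy beyond its three anchored rows, and every waste share
  beyond the two anchored regions, are explicit implementation defaults,
  editable as data.
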