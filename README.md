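# fvgap — fruit-and-vegetable supply, demand and the gap to recommended diets

`fvgap` is an analysis pipeline for a question in food-systems and
nutrition modelling: **will the world supply enough fruits and vegetables
(F&V) for everyone to eat the recommended amount?** It projects per-capita
F&V availability to 2050 with a partial-equilibrium multimarket model under
SSP-style socioeconomic scenarios, compares it against WHO consumption
targets (the 400 g/person/day minimum and the age-specific 330/480/600 g
levels weighted by each country's population pyramid), quantifies how
household food waste erodes the picture, and classifies implemented food
policies on the Nuffield intervention ladder.

Real inputs for this kind of study (FAO balance sheets, UN pyramids, SSP
projections, the WCRF NOURISHING policy database) are not freely
redistributable, so the pipeline ships with a seeded synthetic world
generator that reproduces their statistical structure — every stage is
fully testable offline.

## The model in brief

Per country *c* and commodity *i*, constant-elasticity demand and supply

```
QD_food = α·N·(y/y0)^εy · P^εp        (εp < 0)
QD_other = λ·QD_food
QS      = β·P^γ · Π(1+g)              (γ > 0)
```

are linked through one world market per commodity; each year the world
price P solves global supply = global demand (unique because excess demand
is strictly decreasing), by bracketed Brent root finding. Availability is
`A = Σ_i QD_food·1e6/(N·365)` g/person/day; consumption after waste is
`C = A·(1−w)`; the age-weighted target is `R = Σ_a N_a r_a / Σ_a N_a` with
r = (330, 480, 600) g for ages 0–4, 5–14, 15+. See `docs/methods.md` for
assumptions, parameter defaults and limitations.

## Worked example

Run the numbered analysis drivers from `analysis/` (each regenerates what
it needs; outputs land in `results/`):

```bash
cd analysis
python 01_generate_world.py
python 02_simulate_scenarios.py
python 04_waste_gap.py
```

which prints, for the default 20-country study world (seed 7):

```
world: 20 countries, 7 regions, 4 commodities, 1961-2050 (base 2010), seed 7
  SSP1: 2050 population 8.50 bn (anchor 8.50 bn), per-capita GDP $34,000 (anchor $34,000)
  SSP2: 2050 population 9.20 bn (anchor 9.20 bn), per-capita GDP $25,000 (anchor $25,000)
  SSP3: 2050 population 9.96 bn (anchor 9.96 bn), per-capita GDP $18,000 (anchor $18,000)
...
2050 global population-weighted availability (g/person/day):
  SSP1:   440.7
  SSP2:   366.1
  SSP3:   302.7
...
countries (of 20) meeting the 400 g minimum, SSP2:
  scheme         1965   1990   2015   2030   2050
  zero             14      8      3      5      8
  regional_fao     11      4      1      3      8
  uniform_15pct     11      4      1      2      8
  uniform_33pct      8      2      0      1      5
```

Reading this: the synthetic world's population and income totals hit the
SSP anchors exactly; 2050 availability is ordered SSP1 > SSP2 > SSP3 —
richer worlds demand, and draw forth, more F&V — and at every snapshot
year, assuming more household waste strictly shrinks the set of countries
whose waste-adjusted consumption still clears 400 g/person/day. (Absolute
levels are properties of the synthetic draws, not of any real country.)

The same pipeline is available as a library call or a CLI:

```python
from fvgap import RunConfig, run_pipeline
manifest = run_pipeline(RunConfig(), "results/run", seed=11)
```

```bash
fvgap run-all --out results/run --seed 11
fvgap validate --out results/run
```

`run_pipeline` writes all stage tables (availability, prices, balances,
targets, gap, summaries, policy counts) plus a manifest with the config
hash, solver settings, clearing residuals and per-file checksums; two runs
with the same config and seed are byte-identical.

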