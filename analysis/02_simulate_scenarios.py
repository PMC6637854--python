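"""Simulate world F&V markets to 2050 under SSP1-3 and report availability.

Solves market-clearing world prices for every year after the 2010 base year
and writes availability.csv, prices.csv and balances_out.csv under results/.
Prints the 2050 global population-weighted availability per scenario —
the central comparative-statics result (richer scenario worlds demand, and
therefore draw forth, more fruits and vegetables).
"""

import pandas as pd
from _common import RESULTS, get_world

from fvgap import market_model as mm


def main():
    world = get_world()
    avail, prices, balances = [], [], []
    for scenario in world.config.scenario_presets:
        res = mm.simulate(world, scenario)
        avail.append(res.availability)
        prices.append(res.prices)
        balances.append(res.quantities)
        rel = (res.prices.set_index(["year", "commodity"])["residual"].abs()
               / res.quantities.groupby(["year", "commodity"])["production"].sum())
        print(f"  {scenario}: solved {res.prices['year'].nunique()} years, "
              f"max relative clearing residual {rel.max():.2e}")
    availability = pd.concat(avail, ignore_index=True)
    availability.to_csv(RESULTS / "availability.csv", index=False)
    pd.concat(prices, ignore_index=True).to_csv(RESULTS / "prices.csv", index=False)
    pd.concat(balances, ignore_index=True).to_csv(RESULTS / "balances_out.csv", index=False)

    print("2050 global population-weighted availability (g/person/day):")
    for scenario in world.config.scenario_presets:
        pop = world.population.query("year == 2050 and scenario == @scenario")
        pop = pop.set_index("country")["total"]
        a = availability.query("year == 2050 and scenario == @scenario")
        a = a.set_index("country")["availability"]
        print(f"  {scenario}: {(a * pop).sum() / pop.sum():7.1f}")
    print(f"written to {RESULTS}/availability.csv, prices.csv, balances_out.csv")


if __name__ == "__main__":
    main()
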