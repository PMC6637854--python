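"""Compute WHO-consistent recommended consumption targets per country-year.

The flat 400 g/person/day minimum and the population-pyramid-weighted
age-specific target (330/480/600 g for ages 0-4 / 5-14 / 15+) are written to
results/targets.csv.  Prints how the age-weighted target drifts upward as
pyramids age between 2010 and 2050.
"""

import pandas as pd
from _common import RESULTS, get_world

from fvgap.recommendations import target_series


def main():
    world = get_world()
    parts = [target_series(world, s) for s in world.config.scenario_presets]
    targets = pd.concat(parts, ignore_index=True)
    targets.to_csv(RESULTS / "targets.csv", index=False)

    print("global mean age-weighted target (g/person/day):")
    for scenario in world.config.scenario_presets:
        t = targets.query("scenario == @scenario")
        pop = world.population.query("scenario == @scenario")[
            ["country", "year", "total"]
        ]
        m = t.merge(pop, on=["country", "year"])
        for year in (2010, 2050):
            sl = m.query("year == @year")
            r = (sl["age_weighted_target"] * sl["total"]).sum() / sl["total"].sum()
            print(f"  {scenario} {year}: {r:6.1f}")
    print(f"written to {RESULTS}/targets.csv")


if __name__ == "__main__":
    main()
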