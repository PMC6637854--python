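"""Generate the synthetic study world and report its headline structure.

Writes the world panel tables under results/world/ and prints the global
population and income anchors reached in 2050 under each SSP scenario,
plus the base-year trade-closure check.
"""

from _common import STUDY_CONFIG, WORLD_DIR

from fvgap.synthetic_world import generate_world


def main():
    world = generate_world(STUDY_CONFIG)
    world.to_csv(WORLD_DIR)
    print(f"world: {STUDY_CONFIG.n_countries} countries, "
          f"{STUDY_CONFIG.n_regions} regions, "
          f"{len(STUDY_CONFIG.commodities)} commodities, "
          f"{STUDY_CONFIG.start_year}-{STUDY_CONFIG.end_year} (base "
          f"{STUDY_CONFIG.base_year}), seed {STUDY_CONFIG.seed}")
    for name, preset in world.scenarios.items():
        pop = world.population.query("year == 2050 and scenario == @name")
        total = pop["total"].sum()
        inc = world.income.query("year == 2050 and scenario == @name")
        merged = inc.merge(pop[["country", "total"]], on="country")
        gdp = (merged["income"] * merged["total"]).sum() / total
        print(f"  {name}: 2050 population {total / 1e9:.2f} bn "
              f"(anchor {preset.global_population_2050 / 1e9:.2f} bn), "
              f"per-capita GDP ${gdp:,.0f} "
              f"(anchor ${preset.global_gdp_per_capita_2050:,.0f})")
    closure = world.balances.groupby("commodity")["net_trade"].sum().abs().max()
    print(f"  base-year trade closure: max |sum net trade| = {closure:.2e} t/yr")
    print(f"written to {WORLD_DIR}")


if __name__ == "__main__":
    main()
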