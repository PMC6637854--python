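"""Seeded synthetic world panels for the fruit-and-vegetable gap analysis.

Real studies of the global F&V gap run on FAOSTAT commodity balance sheets,
UN population pyramids and SSP socioeconomic projections.  None of those can
be redistributed here, so this module generates a small synthetic world with
the same statistical structure: countries grouped into the seven geographic
regions used in global food-security reporting, age-banded population and
per-capita income trajectories per SSP scenario, globally trade-consistent
base-year commodity balances for four F&V commodities (three fruit, one
vegetable), heterogeneous demand/supply elasticities, and a regional
household-waste table.

Everything is driven by a single integer seed; identical configs produce
field-by-field identical panels.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError

#: Seven-region grouping conventionally used for global food-security summaries.
REGION_NAMES = (
    "East Asia and Pacific",
    "South Asia",
    "Former Soviet Union",
    "Middle East and North Africa",
    "Sub-Saharan Africa",
    "Latin America and Caribbean",
    "Europe and North America",
)

#: FAO-style household waste shares.  Only the two anchored values (5% in
#: sub-Saharan Africa, 28% in the regions containing North America and
#: east Asia & Pacific) are fixed by published estimates; the remaining
#: regions default to the mid-range placeholder set on WorldConfig.
ANCHORED_WASTE_SHARES = {
    "Sub-Saharan Africa": 0.05,
    "Europe and North America": 0.28,
    "East Asia and Pacific": 0.28,
}

DEFAULT_COMMODITIES = (
    "fruit_temperate",
    "fruit_tropical",
    "fruit_citrus",
    "vegetables",
)


@dataclass(frozen=True)
class ScenarioPreset:
    """Global anchors of an SSP-like socioeconomic scenario.

    ``global_population_2050`` (persons) and ``global_gdp_per_capita_2050``
    (USD/person/year) pin the world totals the generated trajectories must
    hit; ``productivity_growth_multiplier`` scales exogenous supply growth.
    """

    name: str
    global_population_2050: float
    global_gdp_per_capita_2050: float
    productivity_growth_multiplier: float = 1.0

    def __post_init__(self):
        if self.global_population_2050 <= 0 or self.global_gdp_per_capita_2050 <= 0:
            raise ConfigurationError(
                f"scenario {self.name!r}: population and GDP anchors must be "
                f"strictly positive"
            )
        if self.productivity_growth_multiplier < 0:
            raise ConfigurationError(
                f"scenario {self.name!r}: productivity multiplier must be >= 0"
            )


#: The three SSP presets used throughout: an optimistic/sustainable pathway
#: (8.5 billion people at $34k per capita in 2050), a middle-of-the-road one
#: (9.2 billion at $25k) and a fragmented/pessimistic one (~10 billion at $18k).
SSP_PRESETS = {
    "SSP1": ScenarioPreset("SSP1", 8.5e9, 34_000.0, 1.2),
    "SSP2": ScenarioPreset("SSP2", 9.2e9, 25_000.0, 1.0),
    "SSP3": ScenarioPreset("SSP3", 9.96e9, 18_000.0, 0.8),
}


@dataclass(frozen=True)
class ElasticityRanges:
    """Bounds for drawn elasticities.

    income: income elasticity of food demand, positive, declining with income
    (Engel-consistent).  price: own-price demand elasticity, strictly
    negative.  supply: supply price elasticity, strictly positive — together
    with the negative price elasticity this guarantees strictly monotone
    world excess demand, hence a unique market-clearing price.
    """

    income: tuple[float, float] = (0.2, 1.0)
    price: tuple[float, float] = (-0.8, -0.2)
    supply: tuple[float, float] = (0.2, 0.8)

    def validate(self):
        for name, (lo, hi) in (
            ("income", self.income),
            ("price", self.price),
            ("supply", self.supply),
        ):
            if not lo <= hi:
                raise ConfigurationError(f"elasticity range {name}: lower bound exceeds upper")
        if self.price[1] >= 0:
            raise ConfigurationError(
                f"price elasticity upper bound must be < 0, got {self.price[1]}"
            )
        if self.supply[0] <= 0:
            raise ConfigurationError(
                f"supply elasticity lower bound must be > 0, got {self.supply[0]}"
            )


@dataclass(frozen=True)
class WorldConfig:
    """Configuration for :func:`generate_world`."""

    n_countries: int = 20
    n_regions: int = 7
    base_year: int = 2010
    start_year: int = 1961
    end_year: int = 2050
    scenario_presets: tuple[str, ...] = ("SSP1", "SSP2", "SSP3")
    commodities: tuple[str, ...] = DEFAULT_COMMODITIES
    elasticity_ranges: ElasticityRanges = field(default_factory=ElasticityRanges)
    default_waste_share: float = 0.15
    base_global_population: float = 6.9e9  # world total at the 2010 base year
    seed: int = 0

    def validate(self):
        if self.n_countries < 1:
            raise ConfigurationError(f"n_countries must be >= 1, got {self.n_countries}")
        if self.n_regions < 1:
            raise ConfigurationError(f"n_regions must be >= 1, got {self.n_regions}")
        if self.n_regions > self.n_countries:
            raise ConfigurationError(
                f"n_regions ({self.n_regions}) must not exceed "
                f"n_countries ({self.n_countries})"
            )
        if not (self.start_year < self.base_year < self.end_year):
            raise ConfigurationError(
                f"need start_year < base_year < end_year, got "
                f"{self.start_year}/{self.base_year}/{self.end_year}"
            )
        if not self.scenario_presets:
            raise ConfigurationError("at least one scenario preset is required")
        for name in self.scenario_presets:
            if name not in SSP_PRESETS:
                raise ConfigurationError(
                    f"unknown scenario preset {name!r}; known: {sorted(SSP_PRESETS)}"
                )
        if not self.commodities:
            raise ConfigurationError("at least one commodity is required")
        if not 0 <= self.default_waste_share < 1:
            raise ConfigurationError("default_waste_share must lie in [0, 1)")
        self.elasticity_ranges.validate()

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.start_year, self.end_year + 1)

    def region_names(self) -> list[str]:
        names = list(REGION_NAMES)
        while len(names) < self.n_regions:
            names.append(f"Region {len(names) + 1}")
        return names[: self.n_regions]


@dataclass
class WorldPanel:
    """A generated world: tidy tables keyed on country/year/scenario/commodity.

    countries:    country, region, income_group
    population:   country, year, scenario, age_0_4, age_5_14, age_15plus, total (persons)
    income:       country, year, scenario, income (USD/person/year)
    balances:     country, commodity, production, food_demand, other_demand,
                  net_trade (tonnes/year, base year)
    elasticities: country, commodity, eps_income, eps_price, gamma
    growth:       country, commodity, scenario, growth (1/year exogenous supply growth)
    waste:        region, waste_share (household share of food demand wasted)
    """

    config: WorldConfig
    countries: pd.DataFrame
    population: pd.DataFrame
    income: pd.DataFrame
    balances: pd.DataFrame
    elasticities: pd.DataFrame
    growth: pd.DataFrame
    waste: pd.DataFrame

    @property
    def scenarios(self) -> dict[str, ScenarioPreset]:
        return {name: SSP_PRESETS[name] for name in self.config.scenario_presets}

    @property
    def years(self) -> np.ndarray:
        return self.config.years

    def region_of(self) -> dict[str, str]:
        return dict(zip(self.countries["country"], self.countries["region"]))

    def base_population(self) -> pd.Series:
        """Total population per country at the base year (scenario-invariant)."""
        base = self.population[
            (self.population["year"] == self.config.base_year)
            & (self.population["scenario"] == self.config.scenario_presets[0])
        ]
        return base.set_index("country")["total"]

    # ----- CSV round trip ---------------------------------------------------

    CSV_FILES = (
        "countries.csv",
        "population.csv",
        "income.csv",
        "balances.csv",
        "elasticities.csv",
        "growth.csv",
        "waste.csv",
    )

    def to_csv(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name in self.CSV_FILES:
            getattr(self, name[:-4]).to_csv(outdir / name, index=False)
        manifest = {
            "config": _config_to_dict(self.config),
            "scenario_presets": {
                n: dataclasses.asdict(p) for n, p in self.scenarios.items()
            },
        }
        (outdir / "world_manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n"
        )

    @classmethod
    def from_csv(cls, indir: str | Path) -> "WorldPanel":
        indir = Path(indir)
        manifest = json.loads((indir / "world_manifest.json").read_text())
        config = _config_from_dict(manifest["config"])
        tables = {
            name[:-4]: pd.read_csv(indir / name, float_precision="round_trip")
            for name in cls.CSV_FILES
        }
        return cls(config=config, **tables)


def _config_to_dict(config: WorldConfig) -> dict:
    d = dataclasses.asdict(config)
    d["elasticity_ranges"] = {
        "income": list(config.elasticity_ranges.income),
        "price": list(config.elasticity_ranges.price),
        "supply": list(config.elasticity_ranges.supply),
    }
    d["scenario_presets"] = list(config.scenario_presets)
    d["commodities"] = list(config.commodities)
    return d


def _config_from_dict(d: dict) -> WorldConfig:
    d = dict(d)
    er = d.pop("elasticity_ranges")
    return WorldConfig(
        elasticity_ranges=ElasticityRanges(
            income=tuple(er["income"]),
            price=tuple(er["price"]),
            supply=tuple(er["supply"]),
        ),
        scenario_presets=tuple(d.pop("scenario_presets")),
        commodities=tuple(d.pop("commodities")),
        **d,
    )


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def generate_world(config: WorldConfig) -> WorldPanel:
    """Generate a seeded synthetic world panel.

    Population and income trajectories interpolate exponentially between the
    base year and the 2050 scenario anchors; country-level heterogeneity is
    drawn from seeded log-normals and then rescaled so that world totals hit
    each scenario's global anchor exactly.  Base-year commodity balances are
    closed at the world level (net trades sum to zero per commodity) by
    proportionally rescaling exporters' surpluses.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_countries
    years = config.years
    base = config.base_year

    country_ids = [f"C{i + 1:03d}" for i in range(n)]
    regions = config.region_names()
    region_assign = [regions[i % config.n_regions] for i in range(n)]

    # --- population ---------------------------------------------------------
    pop0 = rng.lognormal(mean=np.log(2e8), sigma=1.0, size=n)
    pop0 *= config.base_global_population / pop0.sum()

    hist_rate = rng.normal(0.020, 0.004, size=n)  # backcast growth, 1961-2010

    presets = {name: SSP_PRESETS[name] for name in config.scenario_presets}
    horizon = config.end_year - base

    # per-country raw future growth shared across scenarios, then rescaled to
    # each scenario's global 2050 anchor
    fut_rate_raw = rng.normal(0.010, 0.005, size=n)
    pop2050 = {}
    for name, preset in presets.items():
        raw = pop0 * np.exp(fut_rate_raw * horizon)
        pop2050[name] = raw * (preset.global_population_2050 / raw.sum())

    # age structure: piecewise-linear band shares through (start, base, end)
    s04_base = rng.uniform(0.05, 0.16, size=n)
    s514_base = rng.uniform(0.10, 0.24, size=n)
    young_start = rng.uniform(1.05, 1.30, size=n)  # younger pyramids historically
    young_end = rng.uniform(0.60, 0.90, size=n)  # ageing toward 2050

    def band_shares(year: int) -> tuple[np.ndarray, np.ndarray]:
        if year <= base:
            f = (base - year) / max(base - config.start_year, 1)
            mult = 1 + (young_start - 1) * f
        else:
            f = (year - base) / max(config.end_year - base, 1)
            mult = 1 + (young_end - 1) * f
        s04 = np.clip(s04_base * mult, 0.01, 0.30)
        s514 = np.clip(s514_base * mult, 0.02, 0.35)
        return s04, s514

    pop_rows = []
    for name in config.scenario_presets:
        rate_fut = np.log(pop2050[name] / pop0) / horizon
        for year in years:
            if year <= base:
                total = pop0 * np.exp(hist_rate * (year - base))
            else:
                total = pop0 * np.exp(rate_fut * (year - base))
            s04, s514 = band_shares(int(year))
            a04 = total * s04
            a514 = total * s514
            a15 = total - a04 - a514  # exact band conservation
            pop_rows.append(
                pd.DataFrame(
                    {
                        "country": country_ids,
                        "year": int(year),
                        "scenario": name,
                        "age_0_4": a04,
                        "age_5_14": a514,
                        "age_15plus": a15,
                        "total": total,
                    }
                )
            )
    population = pd.concat(pop_rows, ignore_index=True)

    # --- income -------------------------------------------------------------
    y0 = rng.lognormal(mean=np.log(8_000.0), sigma=0.9, size=n)
    # convergence-flavoured future shape shared across scenarios so scenario
    # income paths are ordered by their global anchors for every country
    z = (np.log(y0) - np.log(y0).mean()) / max(np.log(y0).std(), 1e-9)
    gy = np.clip(0.022 - 0.006 * z + rng.normal(0, 0.004, size=n), 0.001, 0.06)
    y_shape = y0 * np.exp(gy * horizon)
    gh = rng.normal(0.015, 0.003, size=n)

    inc_rows = []
    for name, preset in presets.items():
        w = pop2050[name]
        scale = preset.global_gdp_per_capita_2050 * w.sum() / (w * y_shape).sum()
        y2050 = y_shape * scale
        rate_fut = np.log(y2050 / y0) / horizon
        for year in years:
            if year <= base:
                inc = y0 * np.exp(gh * (year - base))
            else:
                inc = y0 * np.exp(rate_fut * (year - base))
            inc_rows.append(
                pd.DataFrame(
                    {
                        "country": country_ids,
                        "year": int(year),
                        "scenario": name,
                        "income": inc,
                    }
                )
            )
    income = pd.concat(inc_rows, ignore_index=True)

    # --- base-year balances -------------------------------------------------
    k = len(config.commodities)
    # per-capita F&V availability, g/person/day, mildly increasing with income
    avail = np.exp(rng.normal(np.log(250.0), 0.40, size=n)) * (y0 / 8_000.0) ** 0.2
    avail = np.clip(avail, 60.0, 900.0)
    split = rng.dirichlet(np.full(k, 2.0) + (np.arange(k) == k - 1) * 4.0, size=n)

    qd_food = avail[:, None] * split * pop0[:, None] * 365.0 / 1e6  # tonnes/yr
    lam = rng.uniform(0.05, 0.20, size=(n, k))
    qd_other = lam * qd_food
    qd_total = qd_food + qd_other
    qs = qd_total * np.exp(rng.normal(0.0, 0.25, size=(n, k)))
    nt = qs - qd_total

    # world trade closure: rescale exporters' surpluses so net trades sum to 0
    for j in range(k):
        pos = nt[:, j] > 0
        surplus = nt[pos, j].sum()
        deficit = -nt[~pos, j].sum()
        if surplus > 0:
            nt[pos, j] *= deficit / surplus
        else:  # no exporter drawn: close in autarky
            nt[:, j] = 0.0
        qs[:, j] = qd_total[:, j] + nt[:, j]

    balances = pd.DataFrame(
        {
            "country": np.repeat(country_ids, k),
            "commodity": np.tile(config.commodities, n),
            "production": qs.ravel(),
            "food_demand": qd_food.ravel(),
            "other_demand": qd_other.ravel(),
            "net_trade": nt.ravel(),
        }
    )

    # --- elasticities (Engel-consistent income decline) ----------------------
    er = config.elasticity_ranges
    pct = pd.Series(y0).rank(pct=True).to_numpy()
    ey_country = er.income[1] - (er.income[1] - er.income[0]) * pct
    ey = np.clip(
        ey_country[:, None] + rng.normal(0, 0.05, size=(n, k)),
        er.income[0],
        er.income[1],
    )
    ep = rng.uniform(er.price[0], er.price[1], size=(n, k))
    gam = rng.uniform(er.supply[0], er.supply[1], size=(n, k))
    elasticities = pd.DataFrame(
        {
            "country": np.repeat(country_ids, k),
            "commodity": np.tile(config.commodities, n),
            "eps_income": ey.ravel(),
            "eps_price": ep.ravel(),
            "gamma": gam.ravel(),
        }
    )

    # --- exogenous supply growth ---------------------------------------------
    g_base = rng.uniform(0.005, 0.020, size=(n, k))
    growth_rows = []
    for name, preset in presets.items():
        growth_rows.append(
            pd.DataFrame(
                {
                    "country": np.repeat(country_ids, k),
                    "commodity": np.tile(config.commodities, n),
                    "scenario": name,
                    "growth": (g_base * preset.productivity_growth_multiplier).ravel(),
                }
            )
        )
    growth = pd.concat(growth_rows, ignore_index=True)

    # --- countries, income groups, waste table -------------------------------
    terciles = pd.Series(y0).rank(pct=True)
    income_group = np.where(
        terciles <= 1 / 3, "low", np.where(terciles <= 2 / 3, "middle", "high")
    )
    countries = pd.DataFrame(
        {"country": country_ids, "region": region_assign, "income_group": income_group}
    )
    waste = pd.DataFrame(
        {
            "region": regions,
            "waste_share": [
                ANCHORED_WASTE_SHARES.get(r, config.default_waste_share)
                for r in regions
            ],
        }
    )

    return WorldPanel(
        config=config,
        countries=countries,
        population=population,
        income=income,
        balances=balances,
        elasticities=elasticities,
        growth=growth,
        waste=waste,
    )


# ---------------------------------------------------------------------------
# synthetic policy database
# ---------------------------------------------------------------------------


def generate_policy_db(
    n_records: int,
    seed: int,
    membership,
    fv_fraction: float = 0.22,
    bloc_fraction: float = 0.15,
    countries: list[str] | None = None,
):
    """Generate a seeded synthetic policy database.

    Emulates a NOURISHING-style database of implemented policy actions: each
    record carries a jurisdiction (a country, or one of the regional blocs in
    ``membership``), a NOURISHING category from the shipped taxonomy, and a
    free-text description.  A ``fv_fraction`` share of descriptions mention
    fruit or vegetables (and are therefore picked up by the keyword filter);
    the rest describe general healthy eating.

    Returns a list of :class:`fvgap.policy_review.PolicyRecord`.
    """
    from .policy_review import PolicyRecord, load_taxonomy

    if n_records <= 0:
        raise ConfigurationError(f"n_records must be positive, got {n_records}")
    if not 0 <= fv_fraction <= 1:
        raise ConfigurationError("fv_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    taxonomy = load_taxonomy()
    categories = taxonomy["category"].tolist()
    domains = dict(zip(taxonomy["category"], taxonomy["domain"]))

    blocs = list(membership.blocs)
    if countries is None:
        countries = sorted({c for members in membership.blocs.values() for c in members})

    fv_templates = [
        "school scheme providing a minimum quantity of {kw} daily",
        "subsidy programme promoting increased consumption of {kw}",
        "public procurement standard requiring {kw} servings",
        "media campaign encouraging people to eat more {kw}",
    ]
    generic_templates = [
        "promote healthy eating",
        "national nutrition strategy for balanced diets",
        "restrict marketing of energy-dense foods to children",
        "front-of-pack labelling regulation",
    ]

    records = []
    for i in range(n_records):
        if blocs and rng.random() < bloc_fraction:
            jurisdiction = blocs[rng.integers(len(blocs))]
        else:
            jurisdiction = countries[rng.integers(len(countries))]
        category = categories[rng.integers(len(categories))]
        if rng.random() < fv_fraction:
            kw = ["fruit", "vegetables", "fruits and vegetables"][rng.integers(3)]
            desc = fv_templates[rng.integers(len(fv_templates))].format(kw=kw)
        else:
            desc = generic_templates[rng.integers(len(generic_templates))]
        records.append(
            PolicyRecord(
                id=f"P{i + 1:04d}",
                jurisdiction=jurisdiction,
                nourishing_domain=domains[category],
                nourishing_category=category,
                description=desc,
            )
        )
    return records
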