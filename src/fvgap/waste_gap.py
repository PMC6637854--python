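"""Household-waste adjustment and availability-gap summaries.

Food availability from commodity balances is what reaches households, not
what is eaten: a household-waste share w is removed to obtain consumption,
C = A * (1 - w).  Consumption (or availability, under the zero scheme) is
then compared against the minimum and age-weighted recommended levels, and
results are aggregated to regions / income groups / the world with
population weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AlignmentError, FvGapError, GroupingError
from .synthetic_world import WorldPanel

WASTE_KINDS = ("zero", "uniform", "regional")


@dataclass(frozen=True)
class WasteScheme:
    """A household food-waste assumption.

    kind "zero" leaves availability untouched; "uniform" removes the same
    share everywhere; "regional" looks the share up in a region -> share
    table (FAO-style estimates).
    """

    kind: str
    uniform_share: float = 0.0
    regional_table: dict[str, float] = field(default_factory=dict)
    name: str | None = None

    def __post_init__(self):
        if self.kind not in WASTE_KINDS:
            raise FvGapError(f"waste kind must be one of {WASTE_KINDS}, got {self.kind!r}")
        if self.kind == "uniform" and not 0 <= self.uniform_share < 1:
            raise FvGapError(f"uniform waste share must lie in [0, 1), got {self.uniform_share}")
        for region, w in self.regional_table.items():
            if not 0 <= w < 1:
                raise FvGapError(f"waste share for {region!r} must lie in [0, 1), got {w}")
        if self.name is None:
            label = {
                "zero": "zero",
                "uniform": f"uniform_{round(self.uniform_share * 100)}pct",
                "regional": "regional_fao",
            }[self.kind]
            object.__setattr__(self, "name", label)

    @classmethod
    def zero(cls) -> "WasteScheme":
        return cls(kind="zero")

    @classmethod
    def uniform(cls, share: float) -> "WasteScheme":
        return cls(kind="uniform", uniform_share=share)

    @classmethod
    def regional(cls, table: dict[str, float]) -> "WasteScheme":
        return cls(kind="regional", regional_table=dict(table))

    @classmethod
    def from_world(cls, world: WorldPanel) -> "WasteScheme":
        """Regional scheme using the panel's FAO-style waste table."""
        return cls.regional(dict(zip(world.waste["region"], world.waste["waste_share"])))

    def share_for(self, region: str | None) -> float:
        if self.kind == "zero":
            return 0.0
        if self.kind == "uniform":
            return self.uniform_share
        if region not in self.regional_table:
            raise FvGapError(
                f"region {region!r} missing from regional waste table "
                f"(has {sorted(self.regional_table)})"
            )
        return self.regional_table[region]


def apply_waste(availability, scheme: WasteScheme, region: str | None = None):
    """Waste-adjusted consumption C = A * (1 - w), g/person/day.

    Accepts scalars or arrays of availability; ``region`` is only consulted
    by regional schemes.
    """
    a = np.asarray(availability, dtype=float)
    if np.any(a < 0):
        raise FvGapError("availability must be non-negative")
    c = a * (1.0 - scheme.share_for(region))
    return float(c) if np.isscalar(availability) else c


def gap_table(
    availability: pd.DataFrame,
    targets: pd.DataFrame,
    scheme: WasteScheme,
    world: WorldPanel,
) -> pd.DataFrame:
    """Country-level gap table for one waste scheme.

    ``availability`` must have columns country, year, scenario, availability;
    ``targets`` country, year, scenario, minimum_target, age_weighted_target.
    Output adds consumption, ratio_min, ratio_age and the inclusive pass
    flags (C >= target counts as passing).
    """
    merged = availability.merge(
        targets[["country", "year", "scenario", "minimum_target", "age_weighted_target"]],
        on=["country", "year", "scenario"],
        how="left",
        validate="one_to_one",
    )
    missing = merged[merged["age_weighted_target"].isna()]
    if len(missing):
        keys = missing[["country", "year", "scenario"]].to_records(index=False).tolist()
        raise AlignmentError(
            f"{len(keys)} country-year-scenario keys missing from targets",
            missing=keys[:20],
        )
    region_of = world.region_of()
    unmapped = sorted(set(merged["country"]) - set(region_of))
    if unmapped:
        raise GroupingError(f"countries without region assignment: {unmapped}")
    merged["region"] = merged["country"].map(region_of)
    w = merged["region"].map(lambda r: scheme.share_for(r)).to_numpy()
    merged["waste_share"] = w
    merged["scheme"] = scheme.name
    merged["consumption"] = merged["availability"] * (1.0 - w)
    with np.errstate(divide="ignore"):
        merged["ratio_min"] = np.where(
            merged["minimum_target"] > 0,
            merged["consumption"] / merged["minimum_target"],
            np.inf,
        )
        merged["ratio_age"] = np.where(
            merged["age_weighted_target"] > 0,
            merged["consumption"] / merged["age_weighted_target"],
            np.inf,
        )
    merged["pass_min"] = merged["consumption"] >= merged["minimum_target"]
    merged["pass_age"] = merged["consumption"] >= merged["age_weighted_target"]
    return merged[
        [
            "country",
            "region",
            "year",
            "scenario",
            "scheme",
            "waste_share",
            "availability",
            "consumption",
            "minimum_target",
            "age_weighted_target",
            "ratio_min",
            "ratio_age",
            "pass_min",
            "pass_age",
        ]
    ]


def summarize(
    gap: pd.DataFrame, world: WorldPanel, grouping: str = "region"
) -> pd.DataFrame:
    """Population-weighted aggregates of a country-level gap table.

    grouping: "region", "income_group" or "global".  Group availability and
    consumption are population-weighted means; passing counts are numbers of
    countries whose (waste-adjusted) consumption meets each target, and
    passing population is the population living in those countries.
    """
    if grouping not in ("region", "income_group", "global"):
        raise FvGapError(f"unknown grouping {grouping!r}")
    pop = world.population[["country", "year", "scenario", "total"]].rename(
        columns={"total": "population"}
    )
    df = gap.merge(pop, on=["country", "year", "scenario"], how="left", validate="one_to_one")
    if df["population"].isna().any():
        missing = df.loc[df["population"].isna(), "country"].unique().tolist()
        raise AlignmentError("population missing for countries", missing=missing)
    if grouping == "global":
        df["group"] = "Global"
    elif grouping == "region":
        df["group"] = df["region"]
    else:
        mapping = dict(zip(world.countries["country"], world.countries["income_group"]))
        unmapped = sorted(set(df["country"]) - set(mapping))
        if unmapped:
            raise GroupingError(f"countries without income group: {unmapped}")
        df["group"] = df["country"].map(mapping)

    def agg(chunk: pd.DataFrame) -> pd.Series:
        w = chunk["population"].to_numpy()
        return pd.Series(
            {
                "availability": np.average(chunk["availability"], weights=w),
                "consumption": np.average(chunk["consumption"], weights=w),
                "n_countries": chunk["country"].nunique(),
                "n_pass_min": int(chunk["pass_min"].sum()),
                "n_pass_age": int(chunk["pass_age"].sum()),
                "population": w.sum(),
                "population_pass_min": w[chunk["pass_min"].to_numpy()].sum(),
                "population_pass_age": w[chunk["pass_age"].to_numpy()].sum(),
            }
        )

    keys = ["year", "scenario", "scheme", "group"]
    out = df.groupby(keys, sort=True).apply(agg, include_groups=False).reset_index()
    out["grouping"] = grouping
    for col in ("n_countries", "n_pass_min", "n_pass_age"):
        out[col] = out[col].astype(int)
    return out
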