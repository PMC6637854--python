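"""Recommended fruit-and-vegetable consumption levels.

Two WHO targets are supported: the flat minimum of 400 g/person/day, and an
age-specific set (330 g for ages 0-4, 480 g for 5-14, 600 g for 15+) that is
converted into a single per-country level by weighting each band's
recommendation with the country's population pyramid:

    R = sum_a N_a * r_a / sum_a N_a

so R always lies between the smallest and largest band recommendation and is
invariant to uniform rescaling of the pyramid.
"""

from __future__ import annotations

from collections.abc import Mapping

import numpy as np
import pandas as pd

from .errors import DegeneratePopulationError, FvGapError
from .synthetic_world import WorldPanel

AGE_BANDS = ("0-4", "5-14", "15+")

#: WHO age-specific recommended consumption, g/person/day.
DEFAULT_AGE_RECS: dict[str, float] = {"0-4": 330.0, "5-14": 480.0, "15+": 600.0}

#: WHO minimum recommendation, g/person/day.
DEFAULT_MINIMUM = 400.0

_BAND_COLUMNS = {"0-4": "age_0_4", "5-14": "age_5_14", "15+": "age_15plus"}


def age_weighted_target(
    pyramid: Mapping[str, float], recs: Mapping[str, float] = DEFAULT_AGE_RECS
) -> float:
    """Population-pyramid-weighted recommended consumption, g/person/day.

    ``pyramid`` maps age band -> population; ``recs`` maps age band ->
    recommended g/person/day.  Bands must match; a pyramid summing to zero is
    degenerate.
    """
    missing = set(recs) - set(pyramid)
    if missing:
        raise FvGapError(f"pyramid missing age band(s): {sorted(missing)}")
    extra = set(pyramid) - set(recs)
    if extra:
        raise FvGapError(f"no recommendation for age band(s): {sorted(extra)}")
    bands = list(recs)
    pops = np.asarray([pyramid[b] for b in bands], dtype=float)
    levels = np.asarray([recs[b] for b in bands], dtype=float)
    if np.any(pops < 0):
        raise FvGapError("age-band populations must be non-negative")
    if np.any(levels <= 0):
        raise FvGapError("recommended levels must be strictly positive")
    total = pops.sum()
    if total <= 0:
        raise DegeneratePopulationError("population pyramid sums to zero")
    return float((pops * levels).sum() / total)


def target_series(
    world: WorldPanel,
    scenario: str,
    recs: Mapping[str, float] = DEFAULT_AGE_RECS,
    minimum: float = DEFAULT_MINIMUM,
) -> pd.DataFrame:
    """Per country-year targets for one scenario.

    Returns a tidy frame with columns country, year, scenario,
    minimum_target, age_weighted_target, is_historical.  Historical years
    (at or before the panel base year) use the panel's scenario-independent
    historical pyramid and are flagged; future years use the scenario's
    projected pyramids, so R varies across scenarios only through
    demographics.
    """
    if scenario not in world.config.scenario_presets:
        raise FvGapError(
            f"unknown scenario {scenario!r}; panel has {list(world.config.scenario_presets)}"
        )
    pop = world.population[world.population["scenario"] == scenario]
    levels = np.array([recs[b] for b in AGE_BANDS])
    cols = [_BAND_COLUMNS[b] for b in AGE_BANDS]
    weights = pop[cols].to_numpy()
    totals = weights.sum(axis=1)
    if np.any(totals <= 0):
        raise DegeneratePopulationError("zero-population country-year in panel")
    r = (weights * levels).sum(axis=1) / totals
    out = pop[["country", "year"]].copy()
    out["scenario"] = scenario
    out["minimum_target"] = float(minimum)
    out["age_weighted_target"] = r
    out["is_historical"] = out["year"] <= world.config.base_year
    return out.sort_values(["country", "year"], ignore_index=True)
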