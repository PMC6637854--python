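"""Simplified partial-equilibrium multimarket model of world F&V markets.

The model follows the structure of global agricultural multimarket
simulators: each country holds constant-elasticity demand and supply
functions per commodity, countries are linked through a single integrated
world market per commodity, and for every simulated year the world price is
solved so that global supply equals global demand (market clearing).

Functional forms (per country c, commodity i, year t, world price P):

    food demand    QD_food = alpha * N(t) * (y(t)/y0)^eps_y * P^eps_p
    other demand   QD_other = lambda * QD_food
    supply         QS = beta * P^gamma * prod_{s=t0+1..t} (1 + g(s))

with eps_p < 0 < gamma wherever beta > 0, world excess demand is strictly
decreasing in P, so the clearing price is unique and can be found by
bracketed root finding.  All parameters are calibrated so that the base year
reproduces the panel's balances exactly at P = 1.

"Other demand" is an accounting category (processing and storage losses,
non-food uses) carried as a calibrated proportional share of food demand;
post-harvest losses are considered already netted out of the supply
intercept.  Historical years (at or before the base year) replay the panel's
base-year balances rather than being solved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import CalibrationError, ConvergenceError, FvGapError
from .synthetic_world import WorldPanel

#: grams per tonne / days per year: tonnes/year per person -> g/person/day
_T_PER_YEAR_TO_G_PER_DAY = 1e6 / 365.0

PRICE_BOUNDS = (1e-3, 1e3)
INITIAL_BRACKET = (0.25, 4.0)
CLEARING_TOL_REL = 1e-9  # relative residual accepted by the root finder


@dataclass
class MarketParams:
    """Calibrated model parameters, arrays indexed [country, commodity]."""

    countries: list[str]
    commodities: list[str]
    alpha: np.ndarray        # tonnes/year per person at base prices & income
    lam: np.ndarray          # other demand as share of food demand, >= 0
    beta: np.ndarray         # supply intercept, tonnes/year
    eps_income: np.ndarray
    eps_price: np.ndarray
    gamma: np.ndarray
    base_year: int
    n0: np.ndarray           # base-year population, persons
    y0: np.ndarray           # base-year income, USD/person/year

    def __post_init__(self):
        active = self.beta > 0
        if np.any(self.eps_price >= 0):
            raise CalibrationError("price elasticities must be strictly negative")
        if np.any(self.gamma[active] <= 0):
            raise CalibrationError("supply elasticities must be > 0 where beta > 0")


@dataclass
class Drivers:
    """Exogenous drivers of one simulated year under one scenario."""

    year: int
    scenario: str
    population: np.ndarray       # (n,) persons
    income: np.ndarray           # (n,) USD/person/year
    growth_factor: np.ndarray    # (n, k) cumulative exogenous supply growth


@dataclass
class EquilibriumResult:
    """Solved prices, balances and per-capita availability over a horizon."""

    prices: pd.DataFrame        # year, scenario, commodity, price, residual
    quantities: pd.DataFrame    # year, scenario, country, commodity, production,
                                # food_demand, other_demand, net_trade
    availability: pd.DataFrame  # country, year, scenario, availability (g/p/d)
    solver_settings: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------


def calibrate(world: WorldPanel) -> MarketParams:
    """Calibrate the demand system to the panel's base-year balances.

    alpha = QD_food0 / N0, lambda = QD_other0 / QD_food0 and beta = QS0, so
    that simulating the base year at P = 1 reproduces the balances exactly.
    """
    countries = world.countries["country"].tolist()
    commodities = list(world.config.commodities)
    bal = world.balances.pivot(index="country", columns="commodity")
    el = world.elasticities.pivot(index="country", columns="commodity")

    def grab(frame, col):
        return frame[col].reindex(index=countries)[commodities].to_numpy(dtype=float)

    qd_food0 = grab(bal, "food_demand")
    qd_other0 = grab(bal, "other_demand")
    qs0 = grab(bal, "production")

    undefined = (qd_food0 == 0) & (qd_other0 > 0)
    if np.any(undefined):
        c, i = np.argwhere(undefined)[0]
        raise CalibrationError(
            f"other demand without food demand for {countries[c]}/{commodities[i]}: "
            f"lambda undefined"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        lam = np.where(qd_food0 > 0, qd_other0 / np.where(qd_food0 > 0, qd_food0, 1.0), 0.0)

    n0 = world.base_population().reindex(countries).to_numpy(dtype=float)
    first_scen = world.config.scenario_presets[0]
    inc = world.income[
        (world.income["year"] == world.config.base_year)
        & (world.income["scenario"] == first_scen)
    ].set_index("country")["income"]
    y0 = inc.reindex(countries).to_numpy(dtype=float)

    return MarketParams(
        countries=countries,
        commodities=commodities,
        alpha=qd_food0 / n0[:, None],
        lam=lam,
        beta=qs0,
        eps_income=grab(el, "eps_income"),
        eps_price=grab(el, "eps_price"),
        gamma=grab(el, "gamma"),
        base_year=world.config.base_year,
        n0=n0,
        y0=y0,
    )


def make_drivers(world: WorldPanel, year: int, scenario: str) -> Drivers:
    """Assemble the exogenous drivers of one year under one scenario."""
    countries = world.countries["country"].tolist()
    commodities = list(world.config.commodities)
    pop = world.population[
        (world.population["year"] == year) & (world.population["scenario"] == scenario)
    ].set_index("country")["total"]
    inc = world.income[
        (world.income["year"] == year) & (world.income["scenario"] == scenario)
    ].set_index("country")["income"]
    if pop.empty or inc.empty:
        raise FvGapError(f"no drivers for year={year}, scenario={scenario!r}")
    g = (
        world.growth[world.growth["scenario"] == scenario]
        .pivot(index="country", columns="commodity", values="growth")
        .reindex(index=countries)[commodities]
        .to_numpy(dtype=float)
    )
    dt = max(year - world.config.base_year, 0)
    return Drivers(
        year=year,
        scenario=scenario,
        population=pop.reindex(countries).to_numpy(dtype=float),
        income=inc.reindex(countries).to_numpy(dtype=float),
        growth_factor=(1.0 + g) ** dt,
    )


# ---------------------------------------------------------------------------
# behavioural equations
# ---------------------------------------------------------------------------


def _check_price(price) -> None:
    if np.any(np.asarray(price) <= 0):
        raise FvGapError(f"price must be strictly positive, got {price}")


def _food_demand(params: MarketParams, drivers: Drivers, prices: np.ndarray) -> np.ndarray:
    """(n, k) food demand at a vector of world prices (one per commodity)."""
    _check_price(prices)
    income_term = (drivers.income / params.y0)[:, None] ** params.eps_income
    return (
        params.alpha
        * drivers.population[:, None]
        * income_term
        * prices[None, :] ** params.eps_price
    )


def _supply(params: MarketParams, drivers: Drivers, prices: np.ndarray) -> np.ndarray:
    _check_price(prices)
    return params.beta * drivers.growth_factor * prices[None, :] ** params.gamma


def demand_quantity(
    params: MarketParams, country: str, commodity: str, drivers: Drivers, price: float
) -> float:
    """Food demand (tonnes/year) for one country-commodity at a world price."""
    c = params.countries.index(country)
    i = params.commodities.index(commodity)
    prices = np.ones(len(params.commodities))
    prices[i] = price
    return float(_food_demand(params, drivers, prices)[c, i])


def supply_quantity(
    params: MarketParams, country: str, commodity: str, drivers: Drivers, price: float
) -> float:
    """Supply (tonnes/year) for one country-commodity at a world price."""
    c = params.countries.index(country)
    i = params.commodities.index(commodity)
    prices = np.ones(len(params.commodities))
    prices[i] = price
    return float(_supply(params, drivers, prices)[c, i])


def world_excess_demand(
    params: MarketParams, drivers: Drivers, commodity: str, price: float
) -> float:
    """World demand (food + other) minus world supply at a trial price."""
    i = params.commodities.index(commodity)
    prices = np.ones(len(params.commodities))
    prices[i] = price
    qd = _food_demand(params, drivers, prices) * (1.0 + params.lam)
    qs = _supply(params, drivers, prices)
    return float(qd[:, i].sum() - qs[:, i].sum())


# ---------------------------------------------------------------------------
# solver
# ---------------------------------------------------------------------------


def _solve_commodity_price(excess, commodity: str, year: int) -> float:
    """Bracketed root of a strictly decreasing excess-demand function.

    Starts from the initial bracket and expands geometrically toward the
    configured price bounds before giving up.
    """
    lo, hi = INITIAL_BRACKET
    f_lo, f_hi = excess(lo), excess(hi)
    while f_lo < 0 and lo > PRICE_BOUNDS[0]:
        lo = max(lo / 4.0, PRICE_BOUNDS[0])
        f_lo = excess(lo)
    while f_hi > 0 and hi < PRICE_BOUNDS[1]:
        hi = min(hi * 4.0, PRICE_BOUNDS[1])
        f_hi = excess(hi)
    if f_lo < 0 or f_hi > 0:
        residual = f_lo if f_lo < 0 else f_hi
        raise ConvergenceError(
            f"no market-clearing price for {commodity!r} in year {year} within "
            f"price bounds {PRICE_BOUNDS}; residual {residual:.3g}",
            commodity=commodity,
            year=year,
            residual=residual,
        )
    if f_lo == 0:
        return lo
    if f_hi == 0:
        return hi
    return float(brentq(excess, lo, hi, xtol=1e-13, rtol=1e-12))


def solve_year(
    params: MarketParams,
    drivers: Drivers,
    cross_elasticity: np.ndarray | None = None,
    damping: float = 0.5,
    max_iter: int = 500,
    tol: float = 1e-8,
) -> dict:
    """Solve world prices for one year; returns a dict of arrays.

    With the default own-price-only demand, commodities are separable and
    each price is found independently by bracketed root finding.  With a
    cross-price elasticity matrix the solver switches to damped fixed-point
    iteration on the price vector.
    """
    k = len(params.commodities)

    def own_price_solve(base_prices: np.ndarray) -> np.ndarray:
        out = np.empty(k)
        for i, commodity in enumerate(params.commodities):

            def excess(p, i=i):
                prices = base_prices.copy()
                prices[i] = p
                if cross_elasticity is not None:
                    cross_term = float(np.prod(prices ** cross_elasticity[i]))
                else:
                    cross_term = 1.0
                qd = _food_demand(params, drivers, prices) * (1.0 + params.lam)
                qs = _supply(params, drivers, prices)
                return float((qd[:, i] * cross_term).sum() - qs[:, i].sum())

            total_beta = (params.beta[:, i] * drivers.growth_factor[:, i]).sum()
            if total_beta == 0 and excess(1.0) == 0:
                out[i] = 1.0  # inactive market
                continue
            out[i] = _solve_commodity_price(excess, commodity, drivers.year)
        return out

    prices = np.ones(k)
    if cross_elasticity is None:
        prices = own_price_solve(prices)
    else:
        cross_elasticity = np.asarray(cross_elasticity, dtype=float)
        if cross_elasticity.shape != (k, k):
            raise FvGapError(f"cross elasticity matrix must be {(k, k)}")
        for _ in range(max_iter):
            new = own_price_solve(prices)
            step = damping * new + (1 - damping) * prices
            if np.max(np.abs(step - prices) / np.maximum(prices, 1e-12)) < tol:
                prices = step
                break
            prices = step
        else:
            raise ConvergenceError(
                f"cross-price fixed point did not converge in {max_iter} iterations "
                f"for year {drivers.year}",
                year=drivers.year,
            )

    qd_food = _food_demand(params, drivers, prices)
    if cross_elasticity is not None:
        cross_mult = np.prod(prices[None, :] ** cross_elasticity, axis=1)  # (k,)
        qd_food = qd_food * cross_mult[None, :]
    qd_other = params.lam * qd_food
    qs = _supply(params, drivers, prices)
    residual = (qd_food + qd_other).sum(axis=0) - qs.sum(axis=0)
    return {
        "prices": prices,
        "residual": residual,
        "food_demand": qd_food,
        "other_demand": qd_other,
        "production": qs,
        "net_trade": qs - qd_food - qd_other,
    }


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------


def simulate(
    world: WorldPanel,
    scenario: str,
    years=None,
    fv_commodities=None,
    cross_elasticity: np.ndarray | None = None,
) -> EquilibriumResult:
    """Recursive-dynamic simulation of one scenario over a span of years.

    Historical years (<= base year) replay the panel's base-year balances at
    P = 1; future years are solved for market-clearing world prices with the
    year's exogenous drivers.  Per-capita F&V availability is computed from
    food demand:  A = sum_i QD_food(c, i) * 1e6 / (N(c) * 365)  g/person/day.
    """
    if scenario not in world.config.scenario_presets:
        raise FvGapError(
            f"unknown scenario {scenario!r}; panel has {list(world.config.scenario_presets)}"
        )
    params = calibrate(world)
    if years is None:
        years = world.years
    years = [int(y) for y in years]
    lo, hi = world.config.start_year, world.config.end_year
    bad = [y for y in years if not lo <= y <= hi]
    if bad:
        raise FvGapError(f"years outside panel horizon [{lo}, {hi}]: {bad}")

    fv = list(fv_commodities) if fv_commodities is not None else params.commodities
    fv_idx = [params.commodities.index(i) for i in fv]

    base_food = params.alpha * params.n0[:, None]  # = QD_food0
    base_other = params.lam * base_food
    base_qs = params.beta

    price_rows, qty_rows, avail_rows = [], [], []
    for year in sorted(years):
        drivers = make_drivers(world, year, scenario)
        if year <= world.config.base_year:
            sol = {
                "prices": np.ones(len(params.commodities)),
                "residual": (base_food + base_other - base_qs).sum(axis=0),
                "food_demand": base_food,
                "other_demand": base_other,
                "production": base_qs,
                "net_trade": base_qs - base_food - base_other,
            }
        else:
            try:
                sol = solve_year(params, drivers, cross_elasticity=cross_elasticity)
            except ConvergenceError as err:
                raise ConvergenceError(
                    f"year {year}, scenario {scenario}: {err}",
                    commodity=err.commodity,
                    year=year,
                    residual=err.residual,
                ) from err

        price_rows.append(
            pd.DataFrame(
                {
                    "year": year,
                    "scenario": scenario,
                    "commodity": params.commodities,
                    "price": sol["prices"],
                    "residual": sol["residual"],
                }
            )
        )
        n, k = sol["food_demand"].shape
        qty_rows.append(
            pd.DataFrame(
                {
                    "year": year,
                    "scenario": scenario,
                    "country": np.repeat(params.countries, k),
                    "commodity": np.tile(params.commodities, n),
                    "production": sol["production"].ravel(),
                    "food_demand": sol["food_demand"].ravel(),
                    "other_demand": sol["other_demand"].ravel(),
                    "net_trade": sol["net_trade"].ravel(),
                }
            )
        )
        per_capita = (
            sol["food_demand"][:, fv_idx].sum(axis=1)
            / drivers.population
            * _T_PER_YEAR_TO_G_PER_DAY
        )
        avail_rows.append(
            pd.DataFrame(
                {
                    "country": params.countries,
                    "year": year,
                    "scenario": scenario,
                    "availability": per_capita,
                }
            )
        )

    return EquilibriumResult(
        prices=pd.concat(price_rows, ignore_index=True),
        quantities=pd.concat(qty_rows, ignore_index=True),
        availability=pd.concat(avail_rows, ignore_index=True),
        solver_settings={
            "price_bounds": PRICE_BOUNDS,
            "initial_bracket": INITIAL_BRACKET,
            "xtol": 1e-13,
            "rtol": 1e-12,
        },
    )
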