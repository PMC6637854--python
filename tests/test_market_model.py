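"""Market model: calibration, behavioural closed forms, solver correctness."""

import numpy as np
import pandas as pd
import pytest

from fvgap import market_model as mm
from fvgap.errors import CalibrationError, ConvergenceError, FvGapError
from fvgap.synthetic_world import WorldConfig, WorldPanel


def build_panel(
    qs0=1000.0,
    qd_food0=1000.0,
    qd_other0=0.0,
    eps_income=1.0,
    eps_price=-0.5,
    gamma=0.5,
    growth=0.0,
    pop=1e6,
    income_future_mult=1.0,
    pop_future_mult=1.0,
    start_year=2008,
    base_year=2010,
    end_year=2014,
):
    """Hand-built one-country, one-commodity panel with constant drivers.

    Future income/population are the base values times the given multipliers,
    so demand shifters are exact and closed forms are checkable.
    """
    config = WorldConfig(
        n_countries=1,
        n_regions=1,
        commodities=("veg",),
        scenario_presets=("SSP2",),
        start_year=start_year,
        base_year=base_year,
        end_year=end_year,
    )
    years = list(range(start_year, end_year + 1))
    pop_rows, inc_rows = [], []
    for y in years:
        mult_p = pop_future_mult if y > base_year else 1.0
        mult_i = income_future_mult if y > base_year else 1.0
        total = pop * mult_p
        pop_rows.append(
            {"country": "C001", "year": y, "scenario": "SSP2",
             "age_0_4": 0.1 * total, "age_5_14": 0.2 * total,
             "age_15plus": 0.7 * total, "total": total}
        )
        inc_rows.append(
            {"country": "C001", "year": y, "scenario": "SSP2", "income": 1000.0 * mult_i}
        )
    return WorldPanel(
        config=config,
        countries=pd.DataFrame(
            [{"country": "C001", "region": "East Asia and Pacific", "income_group": "middle"}]
        ),
        population=pd.DataFrame(pop_rows),
        income=pd.DataFrame(inc_rows),
        balances=pd.DataFrame(
            [{"country": "C001", "commodity": "veg", "production": qs0,
              "food_demand": qd_food0, "other_demand": qd_other0,
              "net_trade": qs0 - qd_food0 - qd_other0}]
        ),
        elasticities=pd.DataFrame(
            [{"country": "C001", "commodity": "veg", "eps_income": eps_income,
              "eps_price": eps_price, "gamma": gamma}]
        ),
        growth=pd.DataFrame(
            [{"country": "C001", "commodity": "veg", "scenario": "SSP2", "growth": growth}]
        ),
        waste=pd.DataFrame([{"region": "East Asia and Pacific", "waste_share": 0.15}]),
    )


class TestCalibration:
    def test_base_year_identity_on_seeded_panel(self, small_world):
        """Simulating the base year returns P = 1 and the base balances."""
        res = mm.simulate(small_world, "SSP2", years=[2010])
        assert (res.prices["price"] == 1.0).all()
        merged = res.quantities.merge(
            small_world.balances, on=["country", "commodity"], suffixes=("", "_base")
        )
        for col in ("production", "food_demand", "other_demand", "net_trade"):
            np.testing.assert_allclose(
                merged[col], merged[f"{col}_base"], rtol=1e-9, atol=1e-9
            )

    def test_other_demand_share_is_a_ratio(self):
        params = mm.calibrate(build_panel(qd_food0=120.0, qd_other0=30.0, qs0=150.0))
        assert params.lam[0, 0] == pytest.approx(0.25)

    def test_zero_production_country_supplies_nothing(self):
        panel = build_panel(qs0=0.0, qd_food0=0.0, qd_other0=0.0)
        params = mm.calibrate(panel)
        assert params.beta[0, 0] == 0.0
        drivers = mm.make_drivers(panel, 2012, "SSP2")
        for price in (0.1, 1.0, 10.0):
            assert mm.supply_quantity(params, "C001", "veg", drivers, price) == 0.0

    def test_other_demand_without_food_demand_is_a_calibration_error(self):
        with pytest.raises(CalibrationError, match="lambda undefined"):
            mm.calibrate(build_panel(qd_food0=0.0, qd_other0=10.0, qs0=10.0))


class TestBehaviouralClosedForms:
    def test_demand_income_response(self):
        """eps_y = 0.5 and a quadrupled income doubles per-capita demand."""
        panel = build_panel(eps_income=0.5, income_future_mult=4.0)
        params = mm.calibrate(panel)
        drivers = mm.make_drivers(panel, 2012, "SSP2")
        assert mm.demand_quantity(params, "C001", "veg", drivers, 1.0) == pytest.approx(
            2.0 * 1000.0, rel=1e-12
        )

    def test_demand_price_response(self):
        """eps_p = -0.5 and a quadrupled price halves demand."""
        panel = build_panel(eps_price=-0.5)
        params = mm.calibrate(panel)
        drivers = mm.make_drivers(panel, 2012, "SSP2")
        assert mm.demand_quantity(params, "C001", "veg", drivers, 4.0) == pytest.approx(
            0.5 * 1000.0, rel=1e-12
        )

    def test_supply_compound_growth(self):
        """g = 2%/year over 10 years at P = 1 compounds to 1.02^10."""
        panel = build_panel(growth=0.02, end_year=2020)
        params = mm.calibrate(panel)
        drivers = mm.make_drivers(panel, 2020, "SSP2")
        assert mm.supply_quantity(params, "C001", "veg", drivers, 1.0) == pytest.approx(
            1000.0 * 1.02**10, rel=1e-12
        )

    def test_nonpositive_price_rejected(self):
        panel = build_panel()
        params = mm.calibrate(panel)
        drivers = mm.make_drivers(panel, 2012, "SSP2")
        with pytest.raises(FvGapError, match="price"):
            mm.demand_quantity(params, "C001", "veg", drivers, 0.0)
        with pytest.raises(FvGapError, match="price"):
            mm.world_excess_demand(params, drivers, "veg", -1.0)


class TestSolver:
    def test_closed_form_toy_price_and_quantity(self):
        """Demand shifter k=2, eps_p=-0.5, gamma=0.5 -> P* = 2, Q = S0*sqrt(2)."""
        panel = build_panel(eps_income=1.0, eps_price=-0.5, gamma=0.5,
                            income_future_mult=2.0)
        res = mm.simulate(panel, "SSP2", years=[2012])
        assert res.prices["price"].iloc[0] == pytest.approx(2.0, rel=1e-8)
        q = res.quantities["production"].iloc[0]
        assert q == pytest.approx(1000.0 * np.sqrt(2.0), rel=1e-8)

    def test_excess_demand_signs_bracket_equilibrium(self):
        panel = build_panel(income_future_mult=2.0)
        params = mm.calibrate(panel)
        drivers = mm.make_drivers(panel, 2012, "SSP2")
        assert mm.world_excess_demand(params, drivers, "veg", 1e-3) > 0
        assert mm.world_excess_demand(params, drivers, "veg", 1e3) < 0
        assert abs(mm.world_excess_demand(params, drivers, "veg", 2.0)) < 1e-9

    def test_solver_agrees_with_bisection_oracle(self):
        """Brent root vs a 60-step bisection on the same bracket, 25 draws."""
        rng = np.random.default_rng(123)
        for _ in range(25):
            d = rng.uniform(0.5, 5.0)
            s = rng.uniform(0.5, 5.0)
            ep = rng.uniform(-0.8, -0.2)
            gam = rng.uniform(0.2, 0.8)

            def excess(p):
                return d * p**ep - s * p**gam

            price = mm._solve_commodity_price(excess, "x", 2020)
            lo, hi = 1e-3, 1e3
            for _ in range(60):
                mid = 0.5 * (lo + hi)
                if excess(mid) > 0:
                    lo = mid
                else:
                    hi = mid
            assert price == pytest.approx(0.5 * (lo + hi), rel=1e-8)
            assert price == pytest.approx((d / s) ** (1 / (gam - ep)), rel=1e-8)

    def test_unclearable_market_raises_convergence_error(self):
        panel = build_panel(qs0=0.0, qd_food0=1000.0, qd_other0=0.0)
        with pytest.raises(ConvergenceError, match="veg"):
            mm.simulate(panel, "SSP2", years=[2012])


class TestSimulate:
    def test_market_clearing_across_future_years(self, small_world):
        res = mm.simulate(small_world, "SSP1", years=range(2011, 2051, 5))
        supply = res.quantities.groupby(["year", "commodity"])["production"].sum()
        residual = res.prices.set_index(["year", "commodity"])["residual"].abs()
        assert (residual <= 1e-6 * supply.reindex(residual.index)).all()

    def test_steady_state_with_constant_drivers(self):
        panel = build_panel(growth=0.0)
        res = mm.simulate(panel, "SSP2")
        assert np.allclose(res.prices["price"], 1.0, rtol=1e-9)
        q = res.quantities.pivot(index="year", columns="commodity", values="food_demand")
        assert np.allclose(q, 1000.0, rtol=1e-9)

    def test_historical_years_replay_base_balances(self, small_world):
        res = mm.simulate(small_world, "SSP3", years=[1995, 2005])
        for year in (1995, 2005):
            sl = res.quantities.query("year == @year")
            merged = sl.merge(small_world.balances, on=["country", "commodity"],
                              suffixes=("", "_base"))
            np.testing.assert_allclose(merged["food_demand"], merged["food_demand_base"])

    def test_availability_homogeneity_in_population(self):
        """Doubling population and all base quantities leaves per-capita
        availability unchanged."""
        a = build_panel(income_future_mult=1.5)
        b = build_panel(qs0=2000.0, qd_food0=2000.0, income_future_mult=1.5, pop=2e6)
        ra = mm.simulate(a, "SSP2", years=[2012]).availability["availability"].iloc[0]
        rb = mm.simulate(b, "SSP2", years=[2012]).availability["availability"].iloc[0]
        assert ra == pytest.approx(rb, rel=1e-9)

    def test_higher_income_path_raises_price_and_consumption(self):
        low = mm.simulate(build_panel(income_future_mult=1.2), "SSP2", years=[2012])
        high = mm.simulate(build_panel(income_future_mult=1.8), "SSP2", years=[2012])
        assert high.prices["price"].iloc[0] > low.prices["price"].iloc[0]
        assert (
            high.quantities["food_demand"].iloc[0]
            > low.quantities["food_demand"].iloc[0]
        )

    def test_all_quantities_nonnegative(self, small_world):
        res = mm.simulate(small_world, "SSP2", years=[2030, 2050])
        assert (res.quantities[["production", "food_demand", "other_demand"]] >= 0).all().all()
        assert (res.availability["availability"] >= 0).all()

    def test_years_outside_horizon_rejected(self, small_world):
        with pytest.raises(FvGapError, match="horizon"):
            mm.simulate(small_world, "SSP2", years=[2085])


class TestCrossPrice:
    def test_zero_cross_matrix_matches_separable_solution(self):
        panel = build_panel(income_future_mult=2.0)
        sep = mm.simulate(panel, "SSP2", years=[2012])
        cross = mm.simulate(panel, "SSP2", years=[2012],
                            cross_elasticity=np.zeros((1, 1)))
        assert cross.prices["price"].iloc[0] == pytest.approx(
            sep.prices["price"].iloc[0], rel=1e-7
        )

    def test_substitution_clears_all_markets(self, small_world):
        k = len(small_world.config.commodities)
        cross = np.full((k, k), 0.05)
        np.fill_diagonal(cross, 0.0)
        res = mm.simulate(small_world, "SSP2", years=[2030], cross_elasticity=cross)
        supply = res.quantities.groupby(["year", "commodity"])["production"].sum()
        residual = res.prices.set_index(["year", "commodity"])["residual"].abs()
        assert (residual <= 1e-5 * supply.reindex(residual.index)).all()
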