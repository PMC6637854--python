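"""End-to-end pipeline: generate -> simulate -> targets -> gap -> policies.

A single :class:`RunConfig` (optionally loaded from YAML) drives all stages
deterministically; every output table named by the stage interfaces is
written as CSV under the output directory together with a run manifest
(config hash, seed, solver settings, residual diagnostics, per-file
checksums).  Two runs with identical config produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import market_model, policy_review, recommendations, waste_gap
from .errors import ConfigurationError, FvGapError, GroupingError
from .synthetic_world import (
    WorldConfig,
    WorldPanel,
    _config_from_dict,
    _config_to_dict,
    generate_policy_db,
    generate_world,
)

DEFAULT_SNAPSHOT_YEARS = (1965, 1990, 2015, 2030, 2050)
DEFAULT_WASTE_SCHEMES = ("zero", "regional", "uniform:0.15", "uniform:0.33")


def parse_waste_scheme(spec: str, world: WorldPanel) -> waste_gap.WasteScheme:
    """Parse a scheme spec string: "zero", "regional" or "uniform:<share>"."""
    if spec == "zero":
        return waste_gap.WasteScheme.zero()
    if spec == "regional":
        return waste_gap.WasteScheme.from_world(world)
    if spec.startswith("uniform:"):
        try:
            share = float(spec.split(":", 1)[1])
        except ValueError as err:
            raise ConfigurationError(f"bad uniform waste share in {spec!r}") from err
        return waste_gap.WasteScheme.uniform(share)
    raise ConfigurationError(
        f"unknown waste scheme {spec!r}; expected 'zero', 'regional' or 'uniform:<share>'"
    )


@dataclass(frozen=True)
class RunConfig:
    """Full pipeline configuration."""

    world: WorldConfig = field(default_factory=WorldConfig)
    scenarios: tuple[str, ...] | None = None  # None -> all presets in the world
    waste_schemes: tuple[str, ...] = DEFAULT_WASTE_SCHEMES
    minimum_target: float = recommendations.DEFAULT_MINIMUM
    age_recs: dict = field(default_factory=lambda: dict(recommendations.DEFAULT_AGE_RECS))
    snapshot_years: tuple[int, ...] = DEFAULT_SNAPSHOT_YEARS
    n_policy_records: int = 120
    policy_fv_fraction: float = 0.22

    def validate(self):
        self.world.validate()
        if not self.waste_schemes:
            raise ConfigurationError("at least one waste scheme is required")
        scen = self.scenarios or self.world.scenario_presets
        unknown = set(scen) - set(self.world.scenario_presets)
        if unknown:
            raise ConfigurationError(
                f"scenario(s) {sorted(unknown)} not in world presets "
                f"{list(self.world.scenario_presets)}"
            )
        if self.minimum_target < 0:
            raise ConfigurationError("minimum_target must be non-negative")
        missing = set(recommendations.AGE_BANDS) - set(self.age_recs)
        if missing:
            raise ConfigurationError(f"age_recs missing band(s) {sorted(missing)}")
        if self.n_policy_records <= 0:
            raise ConfigurationError("n_policy_records must be positive")

    @property
    def active_scenarios(self) -> tuple[str, ...]:
        return tuple(self.scenarios or self.world.scenario_presets)

    # ----- (de)serialisation ------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["world"] = _config_to_dict(self.world)
        d["scenarios"] = list(self.scenarios) if self.scenarios else None
        d["waste_schemes"] = list(self.waste_schemes)
        d["snapshot_years"] = list(self.snapshot_years)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config key(s): {sorted(unknown)}")
        if "world" in d:
            w = d["world"]
            d["world"] = w if isinstance(w, WorldConfig) else _config_from_dict(w)
        if d.get("scenarios") is not None:
            d["scenarios"] = tuple(d["scenarios"])
        if "waste_schemes" in d:
            d["waste_schemes"] = tuple(d["waste_schemes"])
        if "snapshot_years" in d:
            d["snapshot_years"] = tuple(int(y) for y in d["snapshot_years"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ConfigurationError(f"config file {path} must contain a mapping")
        cfg = cls.from_dict(raw)
        cfg.validate()
        return cfg

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def _write(df: pd.DataFrame, path: Path, files: dict) -> None:
    df.to_csv(path, index=False)
    files[path.name] = hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig, outdir: str | Path, seed: int | None = None) -> dict:
    """Execute all pipeline stages and write outputs + manifest under outdir.

    ``seed`` overrides the world config's seed (so one YAML config can be
    re-run at several seeds).  Returns the manifest dict.
    """
    config.validate()
    if seed is not None:
        config = dataclasses.replace(
            config, world=dataclasses.replace(config.world, seed=int(seed))
        )
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: dict[str, str] = {}

    # stage 1: world generation
    world = generate_world(config.world)
    world.to_csv(outdir / "world")

    # stage 2: market simulation per scenario
    avail_parts, price_parts, bal_parts = [], [], []
    residual_diag = {}
    for scenario in config.active_scenarios:
        result = market_model.simulate(world, scenario)
        avail_parts.append(result.availability)
        price_parts.append(result.prices)
        bal_parts.append(result.quantities)
        supply = result.quantities.groupby(["year", "commodity"])["production"].sum()
        res = result.prices.set_index(["year", "commodity"])["residual"].abs()
        residual_diag[scenario] = float((res / supply.clip(lower=1e-12)).max())
    availability = pd.concat(avail_parts, ignore_index=True)
    _write(availability, outdir / "availability.csv", files)
    _write(pd.concat(price_parts, ignore_index=True), outdir / "prices.csv", files)
    _write(pd.concat(bal_parts, ignore_index=True), outdir / "balances_out.csv", files)

    # stage 3: recommended targets
    target_parts = [
        recommendations.target_series(
            world, s, recs=config.age_recs, minimum=config.minimum_target
        )
        for s in config.active_scenarios
    ]
    targets = pd.concat(target_parts, ignore_index=True)
    _write(targets, outdir / "targets.csv", files)

    # stage 4: waste adjustment and gap summaries
    gap_parts, summary_parts = [], []
    for spec in config.waste_schemes:
        scheme = parse_waste_scheme(spec, world)
        gap = waste_gap.gap_table(availability, targets, scheme, world)
        gap_parts.append(gap)
        for grouping in ("region", "global"):
            summary_parts.append(waste_gap.summarize(gap, world, grouping))
    gap_all = pd.concat(gap_parts, ignore_index=True)
    summary_all = pd.concat(summary_parts, ignore_index=True)
    _write(gap_all, outdir / "gap.csv", files)
    _write(summary_all, outdir / "gap_summary.csv", files)

    snap = summary_all[
        (summary_all["year"].isin(config.snapshot_years))
        & (summary_all["scheme"] == parse_waste_scheme(config.waste_schemes[0], world).name)
    ]
    table1 = snap.pivot_table(
        index=["grouping", "group"],
        columns=["scenario", "year"],
        values=["availability", "n_pass_min"],
        observed=True,
    )
    table1.columns = [f"{m}_{s}_{y}" for m, s, y in table1.columns]
    _write(table1.reset_index(), outdir / "table1_like.csv", files)

    # stage 5: policy review on a synthetic policy database
    membership = policy_review.RegionMembership()
    records = generate_policy_db(
        config.n_policy_records,
        seed=config.world.seed + 1,
        membership=membership,
        fv_fraction=config.policy_fv_fraction,
    )
    fv_records = policy_review.filter_fv_policies(records)
    expanded = policy_review.expand_regions(fv_records, membership)
    tab = policy_review.tabulate(expanded, membership.region_map())
    policies_df = pd.DataFrame([dataclasses.asdict(r) for r in records])
    _write(policies_df, outdir / "policies.csv", files)
    _write(tab.by_region_rung.rename(columns={"count": "n_countries"}),
           outdir / "policy_counts.csv", files)
    _write(tab.by_domain, outdir / "policy_domain_counts.csv", files)

    manifest = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.world.seed,
        "scenarios": list(config.active_scenarios),
        "solver": {
            "price_bounds": list(market_model.PRICE_BOUNDS),
            "initial_bracket": list(market_model.INITIAL_BRACKET),
            "clearing_tol_rel": market_model.CLEARING_TOL_REL,
        },
        "max_relative_clearing_residual": residual_diag,
        "n_policies_total": len(records),
        "n_policies_fv": len(fv_records),
        "files": dict(sorted(files.items())),
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return manifest


# ---------------------------------------------------------------------------
# validation of written tables
# ---------------------------------------------------------------------------

_EXPECTED_COLUMNS = {
    "availability.csv": {"country", "year", "scenario", "availability"},
    "targets.csv": {"country", "year", "scenario", "minimum_target", "age_weighted_target"},
    "gap.csv": {"country", "year", "scenario", "scheme", "availability",
                "consumption", "pass_min", "pass_age", "ratio_min", "ratio_age"},
    "gap_summary.csv": {"year", "scenario", "scheme", "group", "availability",
                        "n_countries", "n_pass_min", "population"},
}


def validate_tables(outdir: str | Path) -> dict:
    """Validate pipeline outputs; returns a machine-readable report.

    Checks column schemas, base-year trade closure, the balance identity,
    demographic band conservation, ratio/flag coherence and regional
    partition sums.  Violations are collected, not raised one-by-one.
    """
    outdir = Path(outdir)
    violations: list[dict] = []
    checked: list[str] = []

    def violate(check: str, detail: str):
        violations.append({"check": check, "detail": detail})

    for name, cols in _EXPECTED_COLUMNS.items():
        path = outdir / name
        if not path.exists():
            violate("file_missing", name)
            continue
        df = pd.read_csv(path)
        missing = cols - set(df.columns)
        if missing:
            violate("schema", f"{name}: missing columns {sorted(missing)}")
        checked.append(name)

    world_dir = outdir / "world"
    if (world_dir / "balances.csv").exists():
        bal = pd.read_csv(world_dir / "balances.csv")
        ident = bal["production"] - bal["food_demand"] - bal["other_demand"] - bal["net_trade"]
        scale = bal["production"].abs().clip(lower=1.0)
        if (ident.abs() / scale).max() > 1e-9:
            violate("balance_identity", "net_trade != production - food - other")
        closure = bal.groupby("commodity").apply(
            lambda g: abs(g["net_trade"].sum()) / max(g["production"].abs().sum(), 1e-12),
            include_groups=False,
        )
        bad = closure[closure > 1e-6]
        if len(bad):
            violate("trade_closure", f"commodities not closed: {bad.to_dict()}")
        checked.append("world/balances.csv")
    if (world_dir / "population.csv").exists():
        pop = pd.read_csv(world_dir / "population.csv")
        err = (pop["age_0_4"] + pop["age_5_14"] + pop["age_15plus"] - pop["total"]).abs()
        if (err / pop["total"].clip(lower=1.0)).max() > 1e-9:
            violate("band_conservation", "age bands do not sum to totals")
        if (pop[["age_0_4", "age_5_14", "age_15plus", "total"]] < 0).any().any():
            violate("non_negativity", "negative populations")
        checked.append("world/population.csv")
    if (world_dir / "countries.csv").exists() and (outdir / "gap.csv").exists():
        countries = pd.read_csv(world_dir / "countries.csv")
        gap = pd.read_csv(outdir / "gap.csv")
        unmapped = sorted(set(gap["country"]) - set(countries["country"]))
        if unmapped:
            violate("grouping", f"gap countries missing from region map: {unmapped}")
        finite = gap[np.isfinite(gap["ratio_min"])]
        if not ((finite["ratio_min"] >= 1) == finite["pass_min"]).all():
            violate("ratio_flag_coherence", "pass_min inconsistent with ratio_min")
        checked.append("gap.csv:coherence")
    if (outdir / "gap_summary.csv").exists():
        summary = pd.read_csv(outdir / "gap_summary.csv")
        reg = summary[summary["grouping"] == "region"]
        glo = summary[summary["grouping"] == "global"]
        if len(reg) and len(glo):
            keys = ["year", "scenario", "scheme"]
            s = reg.groupby(keys)["population"].sum().rename("regional")
            g = glo.set_index(keys)["population"]
            joined = pd.concat([s, g], axis=1).dropna()
            rel = (joined["regional"] - joined["population"]).abs() / joined["population"]
            if rel.max() > 1e-9:
                violate("partition_sum", "regional populations do not sum to global")
            checked.append("gap_summary.csv:partition")

    return {"ok": not violations, "violations": violations, "checked": checked}
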