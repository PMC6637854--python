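"""Policy review: keyword filtering, bloc expansion and Nuffield classification.

Implements the review procedure applied to NOURISHING-style databases of
implemented healthy-diet policies: policies targeting fruits and vegetables
are identified by keyword search on the description, records registered at
regional-bloc level (EU, Caribbean Community, Pacific Island Nations and
Territories) are expanded to all member countries, each NOURISHING category
is mapped to a rung of the Nuffield intervention ladder (ordered from
"provide information", the least forceful, to "eliminate choice", the most
forceful), and results are tabulated as distinct-country counts by region
and rung.

The category -> rung mapping ships as a data file
(``data/nourishing_to_nuffield.csv``) so it can be audited and edited
without touching code.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

from .errors import GroupingError, MembershipError, TaxonomyError

#: The Nuffield intervention ladder, least to most forceful.  The order is
#: fixed and meaningful.
NUFFIELD_RUNGS = (
    "provide information",
    "enable choice",
    "guide choice by changing default",
    "guide choice with incentives",
    "guide choice with disincentives",
    "restrict choice",
    "eliminate choice",
)

NOURISHING_DOMAINS = (
    "food environment",
    "food system",
    "behaviour change communication",
)

DEFAULT_KEYWORDS = ("fruit", "vegetable")

# Regional blocs used for expanding bloc-level policies to countries
# (EU with 28 members, Caribbean Community with 15, Pacific Island Nations
# and Territories with 22).
EU_28 = (
    "AUT", "BEL", "BGR", "HRV", "CYP", "CZE", "DNK", "EST", "FIN", "FRA",
    "DEU", "GRC", "HUN", "IRL", "ITA", "LVA", "LTU", "LUX", "MLT", "NLD",
    "POL", "PRT", "ROU", "SVK", "SVN", "ESP", "SWE", "GBR",
)
CARICOM_15 = (
    "ATG", "BHS", "BRB", "BLZ", "DMA", "GRD", "GUY", "HTI", "JAM", "MSR",
    "KNA", "LCA", "VCT", "SUR", "TTO",
)
PACIFIC_22 = (
    "ASM", "COK", "FJI", "PYF", "GUM", "KIR", "MHL", "FSM", "NRU", "NCL",
    "NIU", "MNP", "PLW", "PNG", "PCN", "WSM", "SLB", "TKL", "TON", "TUV",
    "VUT", "WLF",
)

#: Region label used for each default bloc when tabulating by region.
BLOC_REGIONS = {
    "EU": "Europe and North America",
    "Caribbean Community": "Latin America and Caribbean",
    "Pacific Island Nations and Territories": "East Asia and Pacific",
}


@dataclass(frozen=True)
class RegionMembership:
    """Bloc name -> member country codes."""

    blocs: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: {
            "EU": EU_28,
            "Caribbean Community": CARICOM_15,
            "Pacific Island Nations and Territories": PACIFIC_22,
        }
    )

    def __post_init__(self):
        for name, members in self.blocs.items():
            if not members:
                raise MembershipError(f"bloc {name!r} has no members")

    def countries(self) -> list[str]:
        return sorted({c for members in self.blocs.values() for c in members})

    def region_map(self) -> dict[str, str]:
        """Country -> region for the default blocs (for tabulation demos)."""
        out = {}
        for bloc, members in self.blocs.items():
            region = BLOC_REGIONS.get(bloc, bloc)
            for c in members:
                out[c] = region
        return out


@dataclass(frozen=True)
class PolicyRecord:
    """One implemented-policy entry of a NOURISHING-style database."""

    id: str
    jurisdiction: str
    nourishing_domain: str
    nourishing_category: str
    description: str
    source_bloc: str | None = None  # set when expanded from a bloc record


_taxonomy_cache: pd.DataFrame | None = None


def load_taxonomy() -> pd.DataFrame:
    """Load and validate the category -> (domain, rung) mapping table.

    Totality is asserted at load time: every category appears exactly once,
    every rung is a Nuffield rung, every domain is a NOURISHING domain.
    """
    global _taxonomy_cache
    if _taxonomy_cache is None:
        with (resources.files("fvgap") / "data" / "nourishing_to_nuffield.csv").open() as fh:
            tax = pd.read_csv(fh)
        dup = tax["category"][tax["category"].duplicated()].tolist()
        if dup:
            raise TaxonomyError(f"duplicate categories in taxonomy: {dup}")
        bad_rung = sorted(set(tax["rung"]) - set(NUFFIELD_RUNGS))
        if bad_rung:
            raise TaxonomyError(f"unknown Nuffield rungs in taxonomy: {bad_rung}")
        bad_dom = sorted(set(tax["domain"]) - set(NOURISHING_DOMAINS))
        if bad_dom:
            raise TaxonomyError(f"unknown NOURISHING domains in taxonomy: {bad_dom}")
        _taxonomy_cache = tax
    return _taxonomy_cache


def map_to_nuffield(category: str) -> str:
    """Map a NOURISHING category to its Nuffield ladder rung."""
    tax = load_taxonomy()
    row = tax[tax["category"] == category]
    if row.empty:
        raise TaxonomyError(
            f"unknown NOURISHING category {category!r}; valid categories: "
            f"{sorted(tax['category'])}"
        )
    return row["rung"].iloc[0]


def filter_fv_policies(
    records: list[PolicyRecord],
    keywords: tuple[str, ...] = DEFAULT_KEYWORDS,
    word_boundary: bool = False,
) -> list[PolicyRecord]:
    """Keep records whose description mentions any keyword.

    Matching is case-insensitive substring by default (so "fruits" and
    "Vegetable" match); with ``word_boundary`` a regex word-boundary match is
    used instead.  Records describing only general healthy eating (no
    keyword hit) are excluded.
    """
    lowered = [k.lower() for k in keywords]
    if word_boundary:
        patterns = [re.compile(rf"\b{re.escape(k)}", re.IGNORECASE) for k in keywords]
        return [r for r in records if any(p.search(r.description) for p in patterns)]
    return [
        r
        for r in records
        if any(k in r.description.lower() for k in lowered)
    ]


def expand_regions(
    records: list[PolicyRecord],
    membership: RegionMembership,
    known_countries: list[str] | None = None,
) -> list[PolicyRecord]:
    """Expand bloc-level records to one record per member country.

    A record whose jurisdiction names a bloc becomes one record per member
    country (the bloc is retained in ``source_bloc``); country-level records
    pass through unchanged.  If ``known_countries`` is given, a jurisdiction
    that is neither a bloc nor a known country raises a membership error.
    """
    out = []
    for rec in records:
        if rec.jurisdiction in membership.blocs:
            for country in membership.blocs[rec.jurisdiction]:
                out.append(
                    PolicyRecord(
                        id=rec.id,
                        jurisdiction=country,
                        nourishing_domain=rec.nourishing_domain,
                        nourishing_category=rec.nourishing_category,
                        description=rec.description,
                        source_bloc=rec.jurisdiction,
                    )
                )
        elif known_countries is not None and rec.jurisdiction not in known_countries:
            raise MembershipError(
                f"jurisdiction {rec.jurisdiction!r} is neither a known bloc "
                f"({sorted(membership.blocs)}) nor a known country"
            )
        else:
            out.append(rec)
    return out


@dataclass
class PolicyTabulation:
    """Counts of qualifying policies by region x Nuffield rung and by domain."""

    by_region_rung: pd.DataFrame  # region, rung, count (all rungs present)
    by_domain: pd.DataFrame       # domain, count

    def counts_for_rung(self, rung: str) -> pd.Series:
        t = self.by_region_rung
        return t[t["rung"] == rung].set_index("region")["count"]


def tabulate(
    records: list[PolicyRecord],
    region_map: dict[str, str],
    count_policies: bool = False,
) -> PolicyTabulation:
    """Tabulate country-level records by region x rung and by domain.

    The counting unit is distinct countries (two policies in the same
    country on the same rung count once); ``count_policies`` switches to
    counting records.  Every Nuffield rung appears in the output, with zero
    rows for rungs without examples.
    """
    regions = sorted(set(region_map.values()))
    rows = []
    for rec in records:
        if rec.jurisdiction not in region_map:
            raise GroupingError(
                f"country {rec.jurisdiction!r} has no region assignment"
            )
        rows.append(
            {
                "region": region_map[rec.jurisdiction],
                "rung": map_to_nuffield(rec.nourishing_category),
                "country": rec.jurisdiction,
                "domain": rec.nourishing_domain,
                "id": rec.id,
            }
        )
    df = pd.DataFrame(rows, columns=["region", "rung", "country", "domain", "id"])

    index = pd.MultiIndex.from_product([regions, NUFFIELD_RUNGS], names=["region", "rung"])
    if df.empty:
        counts = pd.Series(0, index=index)
        by_domain = pd.DataFrame(
            {"domain": list(NOURISHING_DOMAINS), "count": 0}
        )
    else:
        unit = "id" if count_policies else "country"
        counts = (
            df.groupby(["region", "rung"])[unit].nunique().reindex(index, fill_value=0)
        )
        dom = df.groupby("domain")[unit].nunique()
        by_domain = (
            dom.reindex(list(NOURISHING_DOMAINS), fill_value=0)
            .rename("count")
            .reset_index()
        )
    by_region_rung = counts.rename("count").reset_index()
    # preserve ladder order in the output
    by_region_rung["rung"] = pd.Categorical(
        by_region_rung["rung"], categories=NUFFIELD_RUNGS, ordered=True
    )
    by_region_rung = by_region_rung.sort_values(["region", "rung"], ignore_index=True)
    by_region_rung["rung"] = by_region_rung["rung"].astype(str)
    return PolicyTabulation(by_region_rung=by_region_rung, by_domain=by_domain)
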