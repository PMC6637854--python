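"""Classify a synthetic policy database on the Nuffield ladder.

Generates a NOURISHING-style synthetic policy database, keeps the records
that specifically mention fruit or vegetables, expands regional-bloc records
(EU, Caribbean Community, Pacific Island Nations and Territories) to their
member countries, maps each NOURISHING category to its Nuffield-ladder rung
and tabulates distinct-country counts by region and rung.  Writes
policies.csv, policy_counts.csv and policy_domain_counts.csv.
"""

import dataclasses

import pandas as pd
from _common import RESULTS

from fvgap.policy_review import (
    RegionMembership,
    expand_regions,
    filter_fv_policies,
    tabulate,
)
from fvgap.synthetic_world import generate_policy_db

N_RECORDS = 120
FV_FRACTION = 0.22
SEED = 8


def main():
    membership = RegionMembership()
    records = generate_policy_db(N_RECORDS, seed=SEED, membership=membership,
                                 fv_fraction=FV_FRACTION)
    fv = filter_fv_policies(records)
    expanded = expand_regions(fv, membership)
    tab = tabulate(expanded, membership.region_map())

    pd.DataFrame([dataclasses.asdict(r) for r in records]).to_csv(
        RESULTS / "policies.csv", index=False)
    tab.by_region_rung.rename(columns={"count": "n_countries"}).to_csv(
        RESULTS / "policy_counts.csv", index=False)
    tab.by_domain.to_csv(RESULTS / "policy_domain_counts.csv", index=False)

    n_bloc = sum(1 for r in fv if r.jurisdiction in membership.blocs)
    print(f"policies: {len(records)} total, {len(fv)} mention fruit/vegetables "
          f"({n_bloc} at bloc level -> {len(expanded)} country records after expansion)")
    print("distinct countries per Nuffield rung (all regions):")
    per_rung = tab.by_region_rung.groupby("rung", sort=False)["count"].sum()
    for rung, n in per_rung.items():
        print(f"  {rung:<35} {n:>4d}")
    print(f"written to {RESULTS}/policies.csv, policy_counts.csv, policy_domain_counts.csv")


if __name__ == "__main__":
    main()
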