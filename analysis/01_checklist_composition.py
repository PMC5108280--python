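"""Checklist layer: origins, overlap partitions and taxonomic composition.

Summarizes the packaged Ponto-Caspian species table (which donor species
reached which recipient subsystem) and the small demo checklist, writing the
tables under results/. The headline numbers: 42 of the 54 listed
Ponto-Caspian species occur in the North Sea or Baltic Sea, 23 in the Great
Lakes or St. Lawrence River, and only 11 in both recipient systems -- the
asymmetry that motivates comparing observed counts against a
shipping-and-environment null model.
"""

from pathlib import Path

import pandas as pd

from invexpect import datasets
from invexpect.checklist import (
    origin_percentages,
    presence_partition,
    subregion_partition,
    taxonomic_composition,
)

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    table1 = datasets.load_table1()
    print(f"Ponto-Caspian species listed: {len(table1)}")

    systems = presence_partition(
        table1,
        list(datasets.NORTH_BALTIC_SUBREGIONS),
        list(datasets.GREAT_LAKES_SUBREGIONS),
    )
    print(
        f"  in North/Baltic system: {systems.only_a + systems.both}; "
        f"in Great Lakes/St. Lawrence: {systems.only_b + systems.both}; "
        f"in both systems: {systems.both}"
    )
    ns_bs = subregion_partition(table1, "north_sea", "baltic_sea")
    gl_sl = subregion_partition(table1, "great_lakes", "st_lawrence_river")
    partitions = pd.DataFrame(
        [
            ("north_sea_vs_baltic_sea", *ns_bs),
            ("great_lakes_vs_st_lawrence", *gl_sl),
            ("north_baltic_vs_great_lakes_system", *systems),
        ],
        columns=["partition", "only_a", "only_b", "both", "total"],
    )
    partitions.to_csv(RESULTS / "table1_partitions.csv", index=False)
    print(f"  subregion partitions written to {RESULTS / 'table1_partitions.csv'}")

    comp = taxonomic_composition(table1, "class")
    comp_frame = pd.DataFrame(
        [(label, count, pct) for label, (count, pct) in comp.items()],
        columns=["class", "count", "percent"],
    )
    comp_frame.to_csv(RESULTS / "table1_class_composition.csv", index=False)
    top = comp_frame.iloc[0]
    print(f"  largest class: {top['class']} ({top['count']} species, {top['percent']:.0f}%)")

    demo = datasets.load_demo_checklist()
    rows = []
    for exclude in ((), ("Tracheophyta",)):
        label = "excl_tracheophyta" if exclude else "all"
        for region, pct in sorted(origin_percentages(demo, exclude).items()):
            rows.append((label, region, pct))
    pd.DataFrame(rows, columns=["view", "donor_region", "percent"]).to_csv(
        RESULTS / "demo_checklist_origins.csv", index=False
    )
    print(f"  demo checklist origin percentages written (with/without vascular plants)")


if __name__ == "__main__":
    main()
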