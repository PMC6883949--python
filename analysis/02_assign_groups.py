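#!/usr/bin/env python
"""Assign animals to high/low metabolic-efficiency groups from phenotypes.

Applies the selection rules (bulls: RFI beyond +-1 SD with a daily-gain
guard; cows: ECM_w bands with carcass-fat conditions and calving/age
exclusions) to results/data/phenotypes.tsv and writes results/groups.tsv.
"""

from pathlib import Path

import pandas as pd

from lncnet.phenotypes import PopulationStats, assign_groups

DATA = Path("results/data")


def main() -> None:
    records = pd.read_csv(DATA / "phenotypes.tsv", sep="\t")
    stats = pd.read_csv(DATA / "population_stats.tsv", sep="\t").set_index("stat")["value"]
    population = PopulationStats(**{k: float(v) for k, v in stats.items()})

    groups = assign_groups(records, population)
    groups.to_csv("results/groups.tsv", sep="\t", index=False)

    counts = groups["group"].value_counts()
    print("group assignment:", dict(counts))
    merged = groups.merge(records, on="animal_id")
    agree = (merged["group"] == merged["group_true"]).mean()
    print(f"agreement with generating labels: {agree:.1%}")
    for reason, sub in groups.groupby("reason"):
        print(f"  {len(sub):2d}  {reason}")


if __name__ == "__main__":
    main()
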