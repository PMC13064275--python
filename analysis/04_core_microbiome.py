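"""Core microbiome (>= 80% subject prevalence) and Venn partitions.

Core genera per group x site, shared/unique counts across sites within a
group and across smoking groups within a site. Reads results/preprocess/,
writes results/core/.
"""

from pathlib import Path

import pandas as pd

from airway_recovery import core_venn as cv
from airway_recovery import io_preprocess as iop

IN_COHORT = Path("results/cohort")
IN_PRE = Path("results/preprocess")
OUT = Path("results/core")
THRESHOLD = 0.8


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    genus = iop.read_feature_table(IN_PRE / "genus_counts.tsv")
    meta = iop.read_metadata(IN_COHORT / "metadata.tsv").loc[genus.index]

    cores: dict[str, dict[str, set]] = {}
    rows = []
    for (group, site), _ in meta.groupby(["group", "site"]):
        prev = iop.prevalence_by_subject(genus, meta, group, site)
        cs = cv.core_taxa(prev, threshold=THRESHOLD, stratum=f"{group}|{site}")
        cores.setdefault(site, {})[group] = set(cs.members)
        rows.append({"group": group, "site": site, "n_core": len(cs.members),
                     "members": ";".join(sorted(cs.members))})
    core_df = pd.DataFrame(rows)
    print("core genus counts (>= 80% of subjects):")
    print(core_df.pivot(index="site", columns="group", values="n_core"))

    overlap = cv.core_overlap_table(cores)
    for site, sub in overlap.groupby("site"):
        full = sub[sub["region"].str.count("&") == sub["region"].str.count("&").max()]
        print(f"{site}: union {sub['count'].sum()}, "
              f"shared across all groups {int(full['count'].sum())}")

    # Venn across sites within each group
    by_group: dict[str, dict[str, set]] = {}
    for site, groups in cores.items():
        for group, members in groups.items():
            by_group.setdefault(group, {})[site] = members
    site_rows = []
    for group, sets in by_group.items():
        if len(sets) < 2:
            continue
        part = cv.venn_partition(sets)
        for pattern, count in part.regions.items():
            site_rows.append({"group": group, "region": "&".join(pattern),
                              "count": count})

    core_df.to_csv(OUT / "core_sets.tsv", sep="\t", index=False)
    overlap.to_csv(OUT / "core_overlap_groups.tsv", sep="\t", index=False)
    pd.DataFrame(site_rows).to_csv(OUT / "core_overlap_sites.tsv", sep="\t",
                                   index=False)
    print(f"wrote {len(list(OUT.iterdir()))} files to {OUT}")


if __name__ == "__main__":
    main()
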