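"""Signed co-occurrence networks over core ASVs per group for oropharynx
and BAL, with the full topology panel and hub taxa.

Reads results/cohort/ + results/preprocess/, writes results/networks/.
"""

from pathlib import Path

import pandas as pd

from airway_recovery import io_preprocess as iop
from airway_recovery import networks as nw

IN_COHORT = Path("results/cohort")
IN_PRE = Path("results/preprocess")
OUT = Path("results/networks")
SITES = ("oropharynx", "BAL")
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    counts = iop.read_feature_table(IN_PRE / "counts_decontaminated.tsv")
    css = pd.read_csv(IN_PRE / "css_normalized.tsv", sep="\t", index_col=0).T
    meta = iop.read_metadata(IN_COHORT / "metadata.tsv").loc[counts.index]

    records, hubs, edges = {}, {}, []
    for site in SITES:
        for group in sorted(meta.loc[meta["site"] == site, "group"].unique()):
            key = f"{group}|{site}"
            try:
                core = nw.core_asv_filter(counts, meta, group, site, threshold=0.5)
                g = nw.build_network(css.loc[core.index, core.columns],
                                     r_threshold=0.3)
            except ValueError as e:
                print(f"{key}: skipped ({e})")
                continue
            records[key] = nw.topology(g, seed=SEED)
            hubs[key] = nw.detect_hubs(g)
            ef = nw.edge_list(g)
            ef.insert(0, "stratum", key)
            edges.append(ef)

    metrics, jaccard = nw.compare_networks(records, hubs)
    print("topology panel (columns = group|site):")
    print(metrics.round(3))
    print("hub-set Jaccard overlap:")
    print(jaccard.round(2))

    metrics.rename_axis("metric").to_csv(OUT / "network_topology.tsv", sep="\t",
                                         float_format="%.10g")
    jaccard.rename_axis("stratum").to_csv(OUT / "hub_jaccard.tsv", sep="\t",
                                          float_format="%.10g")
    pd.DataFrame([{"stratum": k, "hubs": ";".join(sorted(v))}
                  for k, v in hubs.items()]).to_csv(OUT / "hub_taxa.tsv",
                                                    sep="\t", index=False)
    pd.concat(edges, ignore_index=True).to_csv(OUT / "network_edges.tsv",
                                               sep="\t", index=False,
                                               float_format="%.10g")
    print(f"wrote {len(list(OUT.iterdir()))} files to {OUT}")


if __name__ == "__main__":
    main()
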