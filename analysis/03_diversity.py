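"""Alpha/beta diversity, PERMANOVA with subject strata, individuality,
recovery trajectories, within-subject site distances, log-fold baselines.

Reads results/cohort/ + results/preprocess/, writes results/diversity/.
"""

import dataclasses
from pathlib import Path

import pandas as pd
from skbio import TreeNode

from airway_recovery import diversity as dv
from airway_recovery import io_preprocess as iop

IN_COHORT = Path("results/cohort")
IN_PRE = Path("results/preprocess")
OUT = Path("results/diversity")
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    counts = iop.read_feature_table(IN_PRE / "counts_decontaminated.tsv")
    meta = iop.read_metadata(IN_COHORT / "metadata.tsv").loc[counts.index]
    tree = TreeNode.read(str(IN_COHORT / "tree.nwk"), convert_underscores=False)
    css = pd.read_csv(IN_PRE / "css_normalized.tsv", sep="\t", index_col=0).T
    genus_css = pd.read_csv(IN_PRE / "genus_css.tsv", sep="\t", index_col=0).T

    alpha = pd.DataFrame({
        "observed_richness": counts.apply(dv.observed_richness, axis=1),
        "pielou_evenness": counts.apply(dv.pielou_evenness, axis=1),
    }).join(meta[["subject_id", "site", "group"]])
    print("median richness by site:")
    print(alpha.groupby("site")["observed_richness"].median())

    bc = dv.bray_curtis(css)
    wu = dv.weighted_unifrac(counts, tree)
    perm = dv.permanova(wu, meta["site"].values, strata=meta["subject_id"].values,
                        n_perm=999, seed=SEED)
    print(f"PERMANOVA site (strata=subject): pseudo-F {perm.pseudo_F:.1f}, "
          f"R2 {perm.r2:.2f}, p {perm.p_value:.4f}")

    indiv, _ = dv.individuality(wu, meta)
    print("mean individuality by site x group:")
    print(indiv.groupby(["site", "group"])["score"].mean().unstack().round(3))

    recov, _ = dv.recovery_trajectory(bc, meta, baseline_group="NS")
    print("mean similarity to NS baseline by site x group:")
    print(recov.groupby(["site", "group"])["similarity"].mean().unstack().round(3))

    spd, info = dv.site_pair_distance(wu, meta, "oropharynx", "BAL")
    print("within-subject oropharynx-BAL weighted UniFrac by group:")
    print(spd.groupby("group")["distance"].mean().round(3))

    lfc = dv.logfold_to_baseline(genus_css, meta, baseline_group="NS")

    alpha.rename_axis("sample_id").to_csv(OUT / "alpha_diversity.tsv", sep="\t",
                                          float_format="%.10g")
    for name, dm in (("bray_curtis", bc), ("weighted_unifrac", wu)):
        pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).rename_axis(
            "sample_id").to_csv(OUT / f"{name}.tsv", sep="\t", float_format="%.10g")
    pd.DataFrame([dataclasses.asdict(perm)]).to_csv(OUT / "permanova.tsv",
                                                    sep="\t", index=False)
    indiv.to_csv(OUT / "individuality.tsv", sep="\t", index=False,
                 float_format="%.10g")
    recov.to_csv(OUT / "recovery_trajectory.tsv", sep="\t", index=False,
                 float_format="%.10g")
    spd.to_csv(OUT / "site_pair_distance.tsv", sep="\t", index=False,
               float_format="%.10g")
    lfc.rename_axis("sample_id").to_csv(OUT / "logfold_to_baseline.tsv", sep="\t",
                                        float_format="%.10g")
    print(f"wrote {len(list(OUT.iterdir()))} files to {OUT}")


if __name__ == "__main__":
    main()
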