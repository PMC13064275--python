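"""Generate the synthetic smoking-cessation cohort and write it to disk.

The cohort mirrors the emulated study design: 10 never-smokers and 15
smokers followed through cessation (all 15 at six weeks, 5 at one year),
each sampled at nose, oropharynx and BAL, with 5 blank extraction controls
carrying reagent contaminants. Outputs go to results/cohort/.
"""

from pathlib import Path

from airway_recovery.synthetic_cohort import SimConfig, simulate_cohort, write_fixture

OUT = Path("results/cohort")


def main() -> None:
    cfg = SimConfig(seed=1)
    counts, meta, tree, taxonomy, truth = simulate_cohort(cfg)
    paths = write_fixture((counts, meta, tree, taxonomy, truth), OUT)
    bio = meta[meta["group"] != "blank"]
    print(f"cohort: {len(bio)} biological samples, "
          f"{meta['group'].eq('blank').sum()} blanks, {counts.shape[1]} ASVs")
    print(bio.groupby(["group", "site"]).size().unstack())
    print(f"ground truth: {len(truth.contaminants)} contaminants, "
          f"{len(truth.responders)} responder taxa")
    print("intended site regimes:", truth.site_regimes)
    for name, p in paths.items():
        print(f"  wrote {name}: {p}")


if __name__ == "__main__":
    main()
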