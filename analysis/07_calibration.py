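"""Method-validation experiments: oracles, null calibration, regime and
parameter recovery.

Runs the package's full experiment battery (the same computations
scripts/acceptance.py reports) and writes a tidy summary to
results/calibration/.
"""

import json
from pathlib import Path

from airway_recovery import experiments as ex

OUT = Path("results/calibration")
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    summary = {
        "distance_oracles": ex.distance_oracle_check(n_instances=50, seed=SEED),
        "null_model_calibration": ex.null_model_calibration(
            seeds=tuple(SEED + k for k in range(5))),
        "regime_recovery": ex.regime_recovery(seeds=(SEED + 1, SEED + 2, SEED + 3)),
        "permanova_calibration": ex.permanova_calibration(seed=SEED),
        "individuality_monotonicity": ex.individuality_monotonicity(
            seeds=tuple(SEED + k for k in range(1, 6))),
        "recovery_monotonicity": ex.recovery_monotonicity(seed=SEED + 1),
        "modularity_vs_exhaustive": ex.modularity_vs_exhaustive(seed=SEED),
        "network_fixture_checks": ex.network_fixture_checks(seed=SEED),
        "planted_hub_detection": ex.planted_hub_detection(seed=SEED * 100),
        "contaminant_recovery": ex.contaminant_recovery(
            seeds=tuple(SEED + k for k in range(1, 6))),
        "threshold_grid_check": ex.threshold_grid_check(),
        "pipeline_determinism": ex.pipeline_determinism(seed=SEED),
    }
    (OUT / "calibration_summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True, default=float))
    for name, res in summary.items():
        print(f"{name}: {res}")


if __name__ == "__main__":
    main()
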