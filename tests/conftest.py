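import numpy as np
import pandas as pd
import pytest

from airway_recovery import synthetic_cohort as sc


@pytest.fixture(scope="session")
def tree20():
    return sc.simulate_tree(20, seed=1)


@pytest.fixture(scope="session")
def small_cohort():
    """A small but structurally complete cohort: 3 sites, 4 groups,
    longitudinal smokers, blanks with contaminants."""
    cfg = sc.SimConfig(
        n_taxa_pool=80, depth_mean=2000.0,
        n_subjects_per_group={"NS": 4, "AS": 5, "FS6w": 4, "FS1y": 2},
        contaminant_fraction=0.1, seed=42,
    )
    return cfg, sc.simulate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def toy_table():
    return pd.DataFrame(
        [[5, 0, 3, 2], [1, 1, 1, 1], [0, 4, 0, 6]],
        index=["s1", "s2", "s3"], columns=["t1", "t2", "t3", "t4"],
    )
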