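import numpy as np
import pytest

import m3class as m3


@pytest.fixture(scope="session")
def null_cohort():
    """40-subject cohort with no planted effects, 5 modalities x 20 regions."""
    table, _ = m3.gen_feature_table(
        m3.CohortConfig(n_patients=20, n_controls=20, n_regions=20, seed=11)
    )
    return table


@pytest.fixture(scope="session")
def separated_cohort():
    """Well-separated cohort: d=4 on three regions in three modalities."""
    effects = tuple(
        (region, mod, 4.0)
        for region in (2, 5, 9)
        for mod in ("ALFF", "ReHo", "DC")
    )
    table, truth = m3.gen_feature_table(
        m3.CohortConfig(
            n_patients=15, n_controls=15, n_regions=12, effect_map=effects,
            seed=21,
        )
    )
    return table, truth


@pytest.fixture(scope="session")
def symmetric_image():
    """Noise-free mirror-symmetric 4D series with a 6-label toy atlas."""
    cfg = m3.ImageSimConfig(
        grid_shape=(12, 12, 8), n_volumes=48, tr_seconds=2.0,
        n_atlas_labels=6, noise_sd=0.0, seed=7,
    )
    return m3.gen_timeseries_image(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
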