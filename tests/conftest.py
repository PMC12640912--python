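import numpy as np
import pandas as pd
import pytest

from oculopls.catalog import ParameterCatalog, make_catalog
from oculopls.cohort import CohortTable, OUTCOMES


@pytest.fixture(scope="session")
def tiny_catalog() -> ParameterCatalog:
    """Ten parameters, two per task."""
    return make_catalog({t: 2 for t in
                         ("fixation", "pro_saccade", "anti_saccade",
                          "smooth_pursuit", "okn")})


def build_cohort(catalog, n=6, seed=0, group="HC", missing=()):
    """Small deterministic cohort; ``missing`` lists (row, column) holes."""
    rng = np.random.default_rng(seed)
    frame = pd.DataFrame({
        "id": [f"{group}{i:03d}" for i in range(n)],
        "group": group,
        "sex": ["male" if i % 2 else "female" for i in range(n)],
        "age": rng.uniform(20, 75, n).round(1),
    })
    for o in OUTCOMES:
        frame[o] = rng.uniform(5, 25, n).round(1)
    for name in catalog.names:
        frame[name] = rng.normal(size=n).round(6)
    for row, col in missing:
        frame.loc[row, col] = np.nan
    return CohortTable(frame, catalog)


@pytest.fixture
def tiny_cohort(tiny_catalog):
    return build_cohort(tiny_catalog, n=6, seed=3)


@pytest.fixture(scope="session")
def hc_cohort_small():
    """A reduced HC-style cohort for pipeline-level tests (fast)."""
    from dataclasses import replace

    from oculopls.presets import hc_default
    from oculopls.simulate import generate_cohort

    cfg = replace(hc_default(seed=11), n_participants=120,
                  sex_counts=(70, 50), score_completion={},
                  n_params_per_task={t: 8 for t in
                                     ("fixation", "pro_saccade",
                                      "anti_saccade", "smooth_pursuit",
                                      "okn")},
                  n_informative_params=20,
                  missing_block_rate=0.05, missing_cell_rate=0.01)
    cohort, truth = generate_cohort(cfg)
    return cohort, truth, cfg
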