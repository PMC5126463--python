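import numpy as np
import pandas as pd
import pytest

import dynatrauma as dt


@pytest.fixture(scope="session")
def default_cohort():
    """Study-condition cohort: 70 vs 84 patients, 22 mediators, one
    rho=0.85 block of 10 mediators planted in BD_GE4 for the first two
    8 h windows."""
    cfg = dt.default_config(seed=20260101)
    patients, samples = dt.generate_cohort(cfg)
    return cfg, patients, samples


@pytest.fixture(scope="session")
def cohort_groups(default_cohort):
    _, patients, _ = default_cohort
    return patients.set_index("patient_id")["group"]


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def tiny_binned():
    """Balanced 2x2 design with known cell values for the hand-computed
    ANOVA decomposition: g1t1={1,3}, g1t2={2,4}, g2t1={3,5}, g2t2={4,6}."""
    rows = []
    cells = {
        ("g1", 1.0): [1.0, 3.0],
        ("g1", 2.0): [2.0, 4.0],
        ("g2", 1.0): [3.0, 5.0],
        ("g2", 2.0): [4.0, 6.0],
    }
    pid = 0
    groups = {}
    for (g, t), vals in cells.items():
        for v in vals:
            pidname = f"{g}_p{pid}"
            rows.append((pidname, t, v))
            groups[pidname] = g
            pid += 1
    df = pd.DataFrame(rows, columns=["patient_id", "time_nominal", "value"])
    return df, groups
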