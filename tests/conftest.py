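import numpy as np
import pandas as pd
import pytest

import pedsignal as ps


def make_table(stage_names, drug, event, ages=None):
    """Small report table from parallel per-report lists."""
    n = len(stage_names)
    return pd.DataFrame(
        {
            "report_id": [f"R{i}" for i in range(n)],
            "age_years": ages if ages is not None else [10.0] * n,
            "nichd_stage": stage_names,
            "drug": np.asarray(drug, dtype=np.int8),
            "event": np.asarray(event, dtype=np.int8),
        }
    )


@pytest.fixture(scope="session")
def desk_study():
    """One full desk-scale study run (50 positive pairs x 5 classes, 500
    negative pairs, 50,000 reports), shared across evaluation tests."""
    cfg = ps.RunConfig(seed=1)
    return ps.run_study(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
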