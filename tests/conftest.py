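import numpy as np
import pandas as pd
import pytest

from trialcua import default_config, generate_cohort


@pytest.fixture(scope="session")
def default_cohort() -> pd.DataFrame:
    """One synthetic cohort at the default (published-summary) configuration."""
    return generate_cohort(default_config(), seed=20260922)


@pytest.fixture()
def degenerate_cohort() -> pd.DataFrame:
    """Every participant within an arm identical: bootstrap must collapse."""
    rows = []
    for arm, n, cost, q in (("TBMT", 5, 22_200.0, 0.085), ("CBMT", 6, 38_200.0, 0.084)):
        for i in range(n):
            rows.append({"participant_id": f"{arm}{i}", "arm": arm, "cost_naira": cost, "qaly": q})
    return pd.DataFrame(rows)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
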