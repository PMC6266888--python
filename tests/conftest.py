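import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import markovpot as mp

settings.register_profile(
    "det",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")


@pytest.fixture(scope="session")
def tn_dataset():
    """Simulated 8-site x 144-month TN-like dataset (negated scale)."""
    return mp.simulate_chain(mp.preset_spec("TN-like", seed=5))


@pytest.fixture(scope="session")
def tn_results(tn_dataset):
    return mp.MarkovPOT(tn_dataset, -1.0).fit()


@pytest.fixture
def small_tail():
    return mp.GPDTail(u=0.0, sigma=1.0, xi=-0.3, lambda_u=0.2)


@pytest.fixture
def obs_csv(tmp_path):
    """A small valid observations CSV with two variables and two sites."""
    path = tmp_path / "obs.csv"
    path.write_text(
        "site,date,variable,value\n"
        "A,1995-01,TN,2.0\n"
        "A,1995-02,TN,1.5\n"
        "A,1995-03,TN,0.9\n"
        "B,1995-01,TN,3.1\n"
        "B,1995-02,TN,2.2\n"
        "A,1995-01,TP,0.05\n"
        "A,1995-02,TP,0.04\n"
    )
    return path
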