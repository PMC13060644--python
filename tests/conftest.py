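import numpy as np
import pandas as pd
import pytest

from combiphos.io import MultiplexMatrix, SampleDesign
from combiphos.simulate import TmtSimConfig, simulate_tmt


@pytest.fixture(scope="session")
def small_sim():
    """300-feature default-noise simulation shared by read-only tests."""
    return simulate_tmt(TmtSimConfig(n_features=300, seed=11))


@pytest.fixture(scope="session")
def default_sim():
    """Default study-scale simulation (2000 features, 10% responsive at |d|=2)."""
    return simulate_tmt(TmtSimConfig(n_features=2000, seed=7))


@pytest.fixture()
def toy_matrix():
    rng = np.random.default_rng(3)
    vals = 2.0 ** rng.normal(20, 2, size=(50, 4))
    df = pd.DataFrame(vals, index=[f"F{i:03d}" for i in range(50)],
                      columns=["126C", "127N", "127C", "128N"])
    return MultiplexMatrix(run_id="run1", intensities=df)


@pytest.fixture()
def design_18plex():
    rows = []
    conditions = ["DMSO", "drugA", "drugB", "comboAB", "drugC", "comboAC"]
    channels = ["126C", "127N", "127C", "128N", "128C", "129N", "129C", "130N",
                "130C", "131N", "131C", "132N", "132C", "133N", "133C", "134N",
                "134C", "135N"]
    i = 0
    for cond in conditions:
        for rep in (1, 2, 3):
            rows.append({"run_id": "run1", "channel_id": channels[i],
                         "sample_id": f"{cond}_r{rep}", "condition": cond,
                         "bio_rep": rep, "injection_rep": 1})
            i += 1
    return SampleDesign(pd.DataFrame(rows))
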