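import numpy as np
import pandas as pd
import pytest

from seqrsa.design import ExperimentDesign, build_pair_table
from seqrsa.simulate import SimulationConfig, generate_design


@pytest.fixture(scope="session")
def config() -> SimulationConfig:
    return SimulationConfig()


@pytest.fixture(scope="session")
def design(config) -> ExperimentDesign:
    return generate_design(config, seed=1)


@pytest.fixture(scope="session")
def pairs(design) -> pd.DataFrame:
    return build_pair_table(design)


@pytest.fixture(scope="session")
def grid_design() -> ExperimentDesign:
    """A fixed, regular design handy for hand-computed expectations."""
    rows = []
    eid = 1
    speeds = [0.5, 0.25, 0.5, 0.25]
    for s in range(4):
        for p in range(5):
            vt = 7.0 + 3.5 * p + 0.25 * s
            rows.append({
                "event_id": eid, "sequence_id": s + 1, "position": p + 1,
                "virtual_time": vt, "real_time": 3.5 * p / speeds[s],
            })
            eid += 1
    return ExperimentDesign(pd.DataFrame(rows))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
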