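import numpy as np
import pandas as pd
import pytest

from gxelder import SimulationConfig, make_panel


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20251001)


@pytest.fixture(scope="session")
def small_cfg():
    """Small, fast scenario with non-trivial signal for smoke-level checks."""
    return SimulationConfig(n=800, m=300, n_blocks=6, h2g=0.2, h2i=0.02, r_ig=0.5)


@pytest.fixture(scope="session")
def small_panel(small_cfg):
    return make_panel(small_cfg, 42)


@pytest.fixture()
def generic_sumstats_frame():
    return pd.DataFrame(
        {
            "SNP": ["rs1", "rs2", "rs3"],
            "A1": ["A", "C", "G"],
            "A2": ["G", "T", "A"],
            "Z": [1.0, -0.5, 2.0],
            "N": [1000, 1000, 1000],
        }
    )
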