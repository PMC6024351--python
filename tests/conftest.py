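import matplotlib

matplotlib.use("Agg")

import numpy as np
import pytest

from cardiomaze import ionic
from cardiomaze.solver import MonodomainParams


@pytest.fixture(scope="session")
def cell_params():
    return ionic.CellParams()


@pytest.fixture(scope="session")
def mono_params():
    return MonodomainParams()


@pytest.fixture(scope="session")
def apd_table(cell_params):
    """APD90 per hypoxia level at the default pacing protocol (shared across
    tests: pacing to steady state is the expensive part)."""
    out = {}
    for atp in (2.0, 3.0, 4.0, 5.0, 6.0):
        trace = ionic.run_paced_cell(atp, params=cell_params, n_beats=5)
        out[atp] = ionic.measure_apd(trace)
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
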