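import numpy as np
import pytest

import gelnmr as g


@pytest.fixture(scope="session")
def suc_params_25():
    return g.nmrd_params_for("SUC", 25.0)


@pytest.fixture(scope="session")
def suc_params_4():
    return g.nmrd_params_for("SUC", 4.0)


@pytest.fixture(scope="session")
def study_grid():
    """31-point acquisition grid: 10 kHz - 20 MHz log-spaced plus 500 MHz."""
    return g.make_frequency_grid(1e4, 2e7, 30, [5e8])


@pytest.fixture(scope="session")
def cpmg_spec_256():
    """CPMG validation acquisition: 100 us echo spacing, 256 echoes."""
    return g.AcquisitionSpec(sequence="CPMG", n_echoes=256)


@pytest.fixture(scope="session")
def suc_t2_components():
    return g.SAMPLE_T2_PARAMS["SUC"]


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
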