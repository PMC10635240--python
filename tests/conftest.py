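import numpy as np
import pytest

from chromascan import ChromatinParams, InstrumentParams, RIModel, build_calibration


@pytest.fixture(scope="session")
def instrument():
    return InstrumentParams()


@pytest.fixture(scope="session")
def ri():
    return RIModel()


@pytest.fixture(scope="session")
def chromatin():
    return ChromatinParams.from_genomic_size(d=2.5)


@pytest.fixture(scope="session")
def calibration(instrument):
    """Shared calibration spanning most of the physical (2, 3) interval."""
    d_grid = np.concatenate([[2.02], np.arange(2.05, 2.96, 0.05), [2.98]])
    return build_calibration(instrument, phi=0.35, nf=200_000.0, d_grid=d_grid)
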