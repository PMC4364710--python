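import numpy as np
import pytest

from dualtr import (
    DEFAULT_PARAMS,
    SequenceParams,
    SweepConfig,
    run_standard_sweep,
)


@pytest.fixture(scope="session")
def params() -> SequenceParams:
    """The study's sequence constants: TR 4/7 ms, TE 3 ms, T1 1420 ms, T2* 450 ms."""
    return DEFAULT_PARAMS


@pytest.fixture(scope="session")
def sweep_result():
    """The standard gradient-phantom sweep at the default 256x256 grid."""
    return run_standard_sweep(SweepConfig())


@pytest.fixture(scope="session")
def small_sweep_result():
    """Same sweep on a 128x128 grid, for structural and determinism checks."""
    return run_standard_sweep(SweepConfig(n=128))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)
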