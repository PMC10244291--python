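import numpy as np
import pytest

from calcalk import ModelParameters, SolverSettings, TABLE_DEFAULTS


@pytest.fixture(scope="session")
def defaults() -> ModelParameters:
    return TABLE_DEFAULTS


@pytest.fixture(scope="session")
def fast() -> SolverSettings:
    """Solver settings used throughout the suite.

    Loose enough to keep multi-10-Myr runs quick; the accuracy contract
    (tolerance halving changes periodicities < 0.1%) is asserted explicitly.
    """
    return SolverSettings(rel_tol=1e-9, abs_tol=1e-12)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20260926)
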