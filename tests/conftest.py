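import numpy as np
import pytest

from localcca import DesignMatrix, build_design, center_columns, memory_design


@pytest.fixture(scope="session")
def memory_X() -> DesignMatrix:
    """The episodic-memory paradigm design: n = 283, p = 4 (I, E, R, C)."""
    return memory_design()


@pytest.fixture(scope="session")
def small_X() -> DesignMatrix:
    """A compact 4-regressor block design for fast neighborhood tests."""
    cycle = 24.0
    starts = 8.0 + cycle * np.arange(7)
    conditions = {
        "A": (starts, 4.0),
        "B": (starts + 6.0, 6.0),
        "C": (starts + 14.0, 4.0),
        "D": (starts + 19.0, 4.0),
    }
    return build_design(conditions, tr=2.0, n_scans=96)


@pytest.fixture(scope="session")
def random_design() -> DesignMatrix:
    """Centered Gaussian design, 30 x 2, for algebraic oracle checks."""
    rng = np.random.default_rng(7)
    X = center_columns(rng.standard_normal((30, 2)))
    return DesignMatrix(X, ("x1", "x2"))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
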