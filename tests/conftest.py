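import numpy as np
import pytest

from nutrilink import reference
from nutrilink.bivlogit import DesignMatrix


@pytest.fixture(scope="session")
def joint_outcomes():
    """The published 2x2 joint counts expanded to one row per child."""
    rows = []
    for (a, u), count in reference.JOINT_COUNTS.items():
        rows.extend([(a, u)] * count)
    return np.array(rows)


@pytest.fixture(scope="session")
def intercept_design(joint_outcomes):
    n = len(joint_outcomes)
    return DesignMatrix(np.ones((n, 1)), ["intercept"])


@pytest.fixture(scope="session")
def two_covariate_design():
    """n=20000 design with an intercept and two binary covariates."""
    rng = np.random.default_rng(20240101)
    n = 20000
    x = np.column_stack(
        [np.ones(n), rng.integers(0, 2, n), rng.integers(0, 2, n)]
    )
    return DesignMatrix(x, ["intercept", "u", "v"])
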