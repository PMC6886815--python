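import numpy as np
import pandas as pd
import pytest

from mapperflow.synthetic import (
    CohortSpec,
    column_spec_for,
    generate_mixed_imbalanced,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def flipped_cohort():
    """Two-group cohort with sign-flipped effects; the planted case where
    local models should beat a global one."""
    spec = CohortSpec(n=600, seed=7, effect_flip=(1.0, -1.0))
    X, y, groups = generate_mixed_imbalanced(spec)
    return X, y, groups, spec


@pytest.fixture(scope="session")
def flipped_colspec():
    return column_spec_for(CohortSpec(n=600, seed=7, effect_flip=(1.0, -1.0)))


@pytest.fixture
def blobs_table():
    """Two well-separated 2-D numeric blobs as a DataFrame (60 points)."""
    g = np.random.default_rng(3)
    a = g.normal(0.0, 0.3, size=(30, 2))
    b = g.normal(0.0, 0.3, size=(30, 2)) + np.array([10.0, 0.0])
    X = np.vstack([a, b])
    return pd.DataFrame(X, columns=["x0", "x1"])


@pytest.fixture
def uniform_line_table():
    """Uniform 1-D data (as a 2-column table with a dead second column)."""
    v = np.linspace(0.0, 1.0, 90)
    g = np.random.default_rng(5)
    return pd.DataFrame({"x0": v, "x1": g.normal(0, 1e-3, size=90)})
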