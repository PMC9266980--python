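import warnings

import numpy as np
import pandas as pd
import pytest

from mirsig import ExpressionMatrix, FixtureSpec, make_profiles


@pytest.fixture(autouse=True)
def _quiet_data_warnings():
    # data-quality warnings (dropped rows, merged duplicates) are expected
    # all over the fixtures; keep test output readable
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


@pytest.fixture(scope="session")
def small_spec() -> FixtureSpec:
    """Scaled-down study conditions for fast unit tests."""
    return FixtureSpec(
        n_cell_types=6, n_mirnas=60, planted_per_type=5, n_samples=20, seed=7
    )


@pytest.fixture(scope="session")
def small_profiles(small_spec):
    return make_profiles(small_spec)


@pytest.fixture(scope="session")
def default_profiles():
    """The full planted-signature study conditions."""
    spec = FixtureSpec(seed=0)
    return make_profiles(spec)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


def random_matrix(rng, n_rows=12, n_cols=6, prefix="m") -> ExpressionMatrix:
    vals = rng.gamma(2.0, 2.0, size=(n_rows, n_cols))
    return ExpressionMatrix(
        pd.DataFrame(
            vals,
            index=[f"{prefix}{i}" for i in range(n_rows)],
            columns=[f"ct{j}" for j in range(n_cols)],
        )
    )
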