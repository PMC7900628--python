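"""Shared fixtures: default geometry and a session-scoped synthetic cohort."""

import numpy as np
import pytest

from contourpass import cohort as ch
from contourpass import stimulus as st

#: master seed for the shared default cohort used across tests
COHORT_SEED = 0


@pytest.fixture(scope="session")
def default_grid():
    return st.build_hex_grid(39, 25, 1.044)


@pytest.fixture(scope="session")
def default_spec():
    return st.StimulusSpec()


@pytest.fixture(scope="session")
def contour_indices(default_grid):
    return st.select_contour_path(default_grid, 12, 60.0)


@pytest.fixture(scope="session")
def small_spec():
    """Small grid for tests where the full 975-element field is overkill."""
    return st.StimulusSpec(n_cols=5, n_rows=4, spacing=1.0,
                           screen_deg=(8.0, 6.0), px_per_deg=10.0,
                           contour_length=2)


@pytest.fixture(scope="session")
def cohort_data():
    """The default two-group study, simulated once per test session."""
    return ch.simulate_cohort(master_seed=COHORT_SEED)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
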