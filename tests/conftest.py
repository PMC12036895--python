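"""Shared fixtures: parameter presets and the expensive simulation runs.

The 1-D and 2-D reaction-diffusion runs are session-scoped so the speed,
positivity, convergence and plaque-area tests (and the acceptance suite)
all share one integration per configuration.
"""

import pytest

from reospread.params import SV5, T3WT
from reospread.pde import simulate_model2_1d, simulate_model3_2d


@pytest.fixture(scope="session")
def t3wt():
    return T3WT


@pytest.fixture(scope="session")
def sv5():
    return SV5


@pytest.fixture(scope="session")
def sim1d_t3wt():
    """Reference 1-D invasion run for T3wt (dx = 0.02 mm, 300 h)."""
    return simulate_model2_1d(T3WT, length_mm=20.0, duration_h=300.0,
                              dx=0.02, n_snapshots=121)


@pytest.fixture(scope="session")
def sim1d_t3wt_coarse():
    """Same run on the twice-coarser grid, for convergence checks."""
    return simulate_model2_1d(T3WT, length_mm=20.0, duration_h=300.0,
                              dx=0.04, n_snapshots=121)


@pytest.fixture(scope="session")
def sim1d_sv5():
    """1-D invasion run for SV5 (faster front, longer domain)."""
    return simulate_model2_1d(SV5, length_mm=25.0, duration_h=300.0,
                              dx=0.02, n_snapshots=121)


@pytest.fixture(scope="session")
def sim2d_t3wt():
    """Reference 2-D plaque run for T3wt (30 mm square, 120 h, dx = 0.1)."""
    return simulate_model3_2d(T3WT)


@pytest.fixture(scope="session")
def sim2d_sv5():
    return simulate_model3_2d(SV5)
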