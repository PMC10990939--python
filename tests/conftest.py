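"""Shared fixtures: a coarse transfer table and a coarse reaction grid.

The table axes cover the query hull of every network test (temperature
differences 0-10 K, both compound-class diffusivities, the full observed
Soret range, flows well beyond the inlet rate in both directions); the
grid resolution (16 x 160 cells) is the documented coarse setting whose
responses agree with finer grids to ~1 %.
"""

import numpy as np
import pytest

from thermotrap.reaction import REFERENCE_RATES, build_reaction_grid
from thermotrap.transfer import build_transfer_table

COARSE_AXES = {
    "delta_T": np.array([0.0, 2.0, 4.0, 6.0, 8.0, 10.0]),
    "D": np.array([0.8e-9, 1.4e-9]),
    "S_T": np.array([1e-3, 4e-3, 8e-3, 12e-3]),
    "Q_in": np.array([0.005, 0.02, 0.1, 0.5, 2.0, 10.0, 40.0]) * 1e-12,
    "s_bot": np.array([0.01, 0.05, 0.1, 0.2, 0.5, 1.0]),
}

#: coarse chamber-solver grid used throughout the tests
SOLVER_KW = dict(nx=16, ny=80)


@pytest.fixture(scope="session")
def coarse_table():
    return build_transfer_table(axes=COARSE_AXES, nx=16, ny=160)


@pytest.fixture(scope="session")
def reaction_grid():
    return build_reaction_grid(REFERENCE_RATES, points_per_decade=3)
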