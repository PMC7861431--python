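"""Shared synthetic study conditions for the test suite.

Desk scale: reduced 22-autosome genome (3-6 Mb per chromosome, 100 kb bins,
~980 bins) at ~4,000 reads/bin — the per-bin depth of a 23M-read sample on
the full 500 kb grid — with a 50-sample panel standing in for the large NIPT
reference set.
"""

import numpy as np
import pytest

import cfcna as cf

DESK_DEPTH = 4_000_000
DESK_PANEL_N = 50


@pytest.fixture(scope="session")
def desk_grid():
    return cf.BinGrid.desk()


@pytest.fixture(scope="session")
def desk_bias(desk_grid):
    return cf.BiasProfile.random(desk_grid, seed=21)


@pytest.fixture(scope="session")
def desk_panel_counts(desk_grid, desk_bias):
    return cf.simulate_panel(desk_grid, DESK_PANEL_N, DESK_DEPTH, desk_bias,
                             seed=22)


@pytest.fixture(scope="session")
def desk_panel(desk_panel_counts):
    return cf.build_panel(desk_panel_counts)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_profile(grid, z=None, e=None, usable=None, sample_id="toy"):
    """A NormalizedProfile from explicit z/e arrays (v set consistently)."""
    n = grid.n_bins
    z = np.zeros(n) if z is None else np.asarray(z, dtype=float)
    e = np.zeros(n) if e is None else np.asarray(e, dtype=float)
    usable = np.ones(n, dtype=bool) if usable is None else usable
    return cf.NormalizedProfile(sample_id=sample_id, grid=grid,
                                usable=usable, v=1.0 + e, z=z, e=e)
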