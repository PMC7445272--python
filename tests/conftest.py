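import numpy as np
import pytest

import gridhead as gh


@pytest.fixture(scope="session")
def short_trajectory():
    """A 5-min trajectory shared by fast tests."""
    return gh.simulate_trajectory(300.0, 100.0, seed=101)


@pytest.fixture(scope="session")
def long_trajectory():
    """A 25-min trajectory for tests that need full arena coverage."""
    return gh.simulate_trajectory(1500.0, 100.0, seed=202)


@pytest.fixture(scope="session")
def grid_session(long_trajectory):
    """Session with one omnidirectional grid cell and one conjunctive cell."""
    grid = gh.make_grid_cell(peak_rate=15.0, cell_id="grid0")
    conj = gh.make_conjunctive_cell(hd_pref=120.0, peak_rate=15.0,
                                    cell_id="conj0")
    cells = [gh.generate_spikes(long_trajectory, grid, seed=7),
             gh.generate_spikes(long_trajectory, conj, seed=8)]
    return gh.Session(long_trajectory, cells)


def make_trajectory(time, x, y, hd, frame_rate=30.0, arena=100.0):
    return gh.Trajectory(np.asarray(time, float), np.asarray(x, float),
                         np.asarray(y, float), np.asarray(hd, float),
                         frame_rate=frame_rate, arena_size=arena)
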