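import numpy as np
import pytest

from gradlab.migration import ConditionDataset, Trajectory


def make_trajectory(points, cell_id="cell", dt_min=30.0):
    """Trajectory from a list of (x, y) pairs at the standard frame interval."""
    points = np.asarray(points, dtype=float)
    return Trajectory(
        cell_id=cell_id,
        times_min=np.arange(points.shape[0]) * dt_min,
        positions_um=points,
    )


@pytest.fixture
def triangle_track():
    """A 3-4-5 step followed by its reverse: PL 10, net displacement 0."""
    return make_trajectory([(0, 0), (3, 4), (0, 0)])


@pytest.fixture
def straight_track():
    return make_trajectory([(0, 0), (10, 0), (20, 0)])


@pytest.fixture
def small_cohort():
    """Three cells with path lengths 5, 20 and 30 µm."""
    tracks = [
        make_trajectory([(0, 0), (3, 4)], "a"),          # PL 5
        make_trajectory([(0, 0), (20, 0)], "b"),         # PL 20 (exactly threshold)
        make_trajectory([(0, 0), (15, 0), (30, 0)], "c"),  # PL 30
    ]
    return ConditionDataset(condition="C", platform="gll", trajectories=tracks)
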