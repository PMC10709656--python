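import numpy as np
import pytest

from contactguide.conditions import CONTROL, SubstrateCondition
from contactguide.synthetic import CellOutline, Trajectory

GD725 = SubstrateCondition(2.0, 2.0, 725.0)


def make_track(positions, dt_min=10.0, condition=CONTROL, cell_id="t", on_pattern=True):
    """Build a trajectory from a list of (x, y) positions on the dt grid."""
    pos = np.asarray(positions, dtype=float)
    times = np.arange(len(pos)) * dt_min
    return Trajectory(
        cell_id=cell_id,
        times_min=times,
        positions_um=pos,
        condition=condition,
        on_pattern=on_pattern,
    )


def straight_track(n_steps, step_xy, **kwargs):
    """A track taking identical steps ``step_xy`` for ``n_steps`` intervals."""
    step = np.asarray(step_xy, dtype=float)
    pos = np.vstack([[0.0, 0.0], np.cumsum(np.tile(step, (n_steps, 1)), axis=0)])
    return make_track(pos, **kwargs)


@pytest.fixture
def unit_square():
    return CellOutline(
        cell_id="sq",
        vertices_um=np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]]),
        condition=CONTROL,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)
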