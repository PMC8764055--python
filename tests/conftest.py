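import numpy as np
import pytest

from invafront.lattice import FrontTrajectory, ModelParams


@pytest.fixture
def params_1d():
    return ModelParams(dimension=1, N=3, box_length=40, n_steps=10, seed=0)


@pytest.fixture
def params_2d():
    return ModelParams(dimension=2, N=3, L=5, box_length=30, n_steps=10,
                       species_count=2, zeta=0.5, seed=0)


def make_trajectory(times, values, params=None, seed=0):
    """Wrap raw arrays as a FrontTrajectory with placeholder parameters."""
    values = np.asarray(values)
    if params is None:
        dim = 1 if values.ndim == 1 else 2
        params = ModelParams(
            dimension=dim, N=1,
            box_length=max(int(np.abs(values).max()) + 2, 4),
            n_steps=int(np.max(times)),
            L=values.shape[1] if values.ndim == 2 else None,
        )
    return FrontTrajectory(times=np.asarray(times, dtype=np.int64),
                           values=values, params=params, seed=seed)
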