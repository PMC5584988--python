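import numpy as np
import pytest

from digdive import ChamberGeometry, Trajectory
from digdive.simulate import preset_params, simulate_trial


@pytest.fixture
def geometry() -> ChamberGeometry:
    return ChamberGeometry()


@pytest.fixture
def mel_trial(geometry):
    """One deterministic melanogaster trial with ground truth."""
    params = preset_params("mel_0.4_noodor")
    return simulate_trial(params, geometry=geometry, seed=11)


def make_trajectory(z, x=None, trial_id="t", dt=1.0, missing=None):
    z = np.asarray(z, dtype=float)
    n = len(z)
    return Trajectory(
        trial_id=trial_id,
        times=np.arange(n) * dt,
        x=np.zeros(n) if x is None else np.asarray(x, dtype=float),
        z=z,
        missing=missing,
    )
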