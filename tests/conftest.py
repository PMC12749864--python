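import numpy as np
import pytest

from poreflux.core import Particle, Trajectory
from poreflux.potential import ChannelPotential, default_channel_potential


@pytest.fixture(scope="session")
def calibrated_potential() -> ChannelPotential:
    """The field-free landscape calibrated to 0.71/6.37/7.52 kcal/mol."""
    return default_channel_potential()


@pytest.fixture(scope="session")
def flat_potential() -> ChannelPotential:
    return ChannelPotential(wells=(), barriers=(), repulsion=None)


def make_trajectory(z_series, times=None, box=(30.0, 30.0, 60.0)):
    """Trajectory from per-ion axial series; x = y = 0."""
    z = np.asarray(z_series, dtype=float)
    if z.ndim == 1:
        z = z[:, None]
    n_frames, n = z.shape
    pos = np.zeros((n_frames, n, 3))
    pos[:, :, 2] = z
    t = np.arange(n_frames, dtype=float) * 0.01 if times is None else np.asarray(times)
    return Trajectory(
        particles=[Particle(i, "NA", 1.0) for i in range(n)],
        times=t,
        positions=pos,
        box=np.tile(np.asarray(box, dtype=float), (n_frames, 1)),
    )


@pytest.fixture()
def traj_factory():
    return make_trajectory
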