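import numpy as np
import pytest

from macchiato.device import droplet_device, sender_device
from macchiato.simulator import SimGrid


@pytest.fixture(scope="session")
def coarse_grid():
    """0.5 mm grid: the resolution used for placement searches."""
    return SimGrid(extent=(35.0, 35.0), spacing=0.5, dt=0.04)


@pytest.fixture(scope="session")
def fine_grid():
    return SimGrid(extent=(35.0, 35.0), spacing=0.25, dt=0.01)


@pytest.fixture(scope="session")
def iptg_device(coarse_grid):
    return droplet_device(grid=coarse_grid)


@pytest.fixture(scope="session")
def hsl_device(coarse_grid):
    return sender_device(grid=coarse_grid)
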