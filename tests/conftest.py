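import math

import numpy as np
import pytest

from mrcytometry import ex_vivo_protocols
from mrcytometry.fitting import SignalModel
from mrcytometry.substrate import Substrate


@pytest.fixture(scope="session")
def protocols():
    """The packaged four-protocol ex-vivo acquisition set."""
    return ex_vivo_protocols()


@pytest.fixture(scope="session")
def signal_model(protocols):
    """Cached forward model over the default protocols (expensive to build)."""
    return SignalModel(protocols)


def disk_substrate(diameter_um, size_px, resolution=0.5, **props):
    """Substrate holding a single centred disk cell."""
    lab = np.zeros((size_px, size_px), dtype=np.int32)
    yy, xx = np.mgrid[:size_px, :size_px]
    r = diameter_um / 2.0
    c = size_px / 2.0 - 0.5
    lab[((yy - c) * resolution) ** 2 + ((xx - c) * resolution) ** 2 <= r * r] = 1
    return Substrate(lab, resolution, **props)


def equivalent_diameter(substrate):
    area = np.count_nonzero(substrate.labels) * substrate.resolution ** 2
    return 2.0 * math.sqrt(area / math.pi)


@pytest.fixture(scope="session")
def small_disk():
    """15 µm impermeable cell in a 64×64 field (fast FD runs)."""
    return disk_substrate(15.0, 64, D_in=1.53, D_ex=2.0, kappa=0.0)
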