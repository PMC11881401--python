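import numpy as np
import pytest

from cmhquant.pipeline import RunConfig
from cmhquant.synthetic import (
    PhantomSpec,
    generate_deposit_channel,
    generate_vessel_phantom,
)


@pytest.fixture(scope="session")
def small_phantom():
    """One modest capillary-profile phantom shared across tests:
    (fluorescence, transmission, truth graph, deposit truth, spec)."""
    spec = PhantomSpec(
        volume_shape=(96, 96, 96), n_vessels=20, n_lesions=3, seed=11
    )
    fluor, truth = generate_vessel_phantom(spec)
    trans, deposits = generate_deposit_channel(spec, truth)
    return fluor, trans, truth, deposits, spec


@pytest.fixture()
def straight_tube_mask():
    """Axis-aligned solid cylinder of diameter 6 µm in a 1 µm lattice."""

    def make(diameter=6.0, shape=(40, 21, 21), axis=0):
        zz, yy, xx = np.mgrid[0 : shape[0], 0 : shape[1], 0 : shape[2]]
        cy, cx = (shape[1] - 1) / 2, (shape[2] - 1) / 2
        mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= (diameter / 2) ** 2
        return mask

    return make


@pytest.fixture()
def default_config():
    return RunConfig()
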