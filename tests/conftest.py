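import numpy as np
import pytest

from clemtarget import phantom as ph
from clemtarget.registration import AffineTransform, CompositeTransform


SMALL_CFG = {
    "extent_um": [60.0, 60.0, 60.0],
    "block_margin_um": 10.0,
}


@pytest.fixture(scope="session")
def small_pair():
    """One fully rendered phantom fixture (60 µm extent), shared across tests."""
    return ph.generate_pair(SMALL_CFG, seed=3)


@pytest.fixture(scope="session")
def small_tree():
    return ph.generate_vessel_tree(extent=(60, 60, 60), seed=3)


@pytest.fixture()
def identity_transform():
    return CompositeTransform(
        [
            AffineTransform(
                np.eye(3), np.zeros(3), kind="rigid",
                source_frame="ivm", target_frame="microct",
            )
        ]
    )


def random_rotation(rng):
    from scipy.spatial.transform import Rotation

    return Rotation.random(random_state=np.random.RandomState(rng.integers(0, 2**31 - 1))).as_matrix()
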