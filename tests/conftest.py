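import numpy as np
import pytest

from rubix import (
    BallParams,
    FibreCompartment,
    GradientScheme,
    KernelParams,
    VoxelParams,
)
from rubix.phantom import make_scheme


@pytest.fixture(scope="session")
def three_shell_scheme() -> GradientScheme:
    """3-shell angularly rich protocol (b = 1000/2000/3000, 90 dirs/shell)."""
    return make_scheme([1000, 2000, 3000], 90, n_b0=5, seed=11)


@pytest.fixture(scope="session")
def two_shell_scheme() -> GradientScheme:
    """2-shell high-resolution protocol (b = 1000/2000, 65 dirs/shell)."""
    return make_scheme([1000, 2000], 65, n_b0=6, seed=12)


@pytest.fixture
def wm_voxel() -> VoxelParams:
    return VoxelParams(
        S0=1000.0,
        ball=BallParams(d_m=1e-3, d_std=1e-4),
        kernel=KernelParams(lambda_m=1e-3, lambda_R=0.13),
        fibres=(FibreCompartment(0.7, np.array([1.0, 0.0, 0.0])),),
    )
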