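import numpy as np
import pytest

from carcingeo.shells import ShellModel, generate_shell


@pytest.fixture(scope="session")
def default_shell():
    """The package-default shell, shared across tests (generation is cheap,
    but placements on it benefit from a warm mesh)."""
    return generate_shell(ShellModel())


@pytest.fixture(scope="session")
def small_shell():
    """A lighter shell for voxelisation tests."""
    return generate_shell(ShellModel(
        n_revolutions=1.75, points_per_revolution=72, aperture_points=32))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
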