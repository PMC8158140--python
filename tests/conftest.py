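import numpy as np
import pytest

from phasecell.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def small_phantom():
    """Clean (noise-free) 96x96 3-frame phantom shared across tests."""
    spec = PhantomSpec(
        frame_shape=(96, 96),
        n_frames=3,
        cell_radius=13.0,
        pseudopod_length=10.0,
        noise_sigma=0.0,
        noise_alpha=0.0,
        halo_gain=0.3,
        seed=7,
    )
    return generate_phantom(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
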