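import numpy as np
import pytest

from polarimap import synthetic


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def uniform_bundle():
    """Noise-free uniform-polarity bundle: 5 filaments in a row, 30 nm apart."""
    spec = synthetic.BundleSpec(
        n_filaments=5, segments_per_filament=20, lattice_spacing=30.0,
        grid_shape=(1, 5), polarity_pattern="uniform", seed=0)
    poses, truth = synthetic.generate_bundle(spec)
    return poses, truth


@pytest.fixture
def checkerboard_bundle():
    """Alternating 4x4 bundle; 30 nm pitch puts same-polarity diagonals
    (42.4 nm) outside the 40 nm neighborhood radius, so every counted
    relation is mixed-polarity."""
    spec = synthetic.BundleSpec(
        n_filaments=16, segments_per_filament=20, lattice_spacing=30.0,
        grid_shape=(4, 4), polarity_pattern="alternating", seed=0)
    poses, truth = synthetic.generate_bundle(spec)
    return poses, truth
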