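import warnings

import numpy as np
import pytest

from dssmlm import sim
from dssmlm.enhancer import EnhancerSpec, train_enhancer
from dssmlm.localizer import LocalizerSpec, train_localizer

warnings.filterwarnings("ignore", message="requested .* training pairs")


@pytest.fixture(scope="session")
def dyes():
    return sim.default_dyes()


@pytest.fixture(scope="session")
def af647(dyes):
    return dyes["AF647"]


@pytest.fixture(scope="session")
def optics():
    """Default 64x64-px labeled-mode configuration."""
    return sim.OpticsConfig()


@pytest.fixture(scope="session")
def wide_optics():
    """128x128-px field used to harvest training patches."""
    return sim.OpticsConfig(fov=(12.8, 12.8))


@pytest.fixture(scope="session")
def calibration(optics):
    return sim.true_calibration(optics)


@pytest.fixture(scope="session")
def small_stack(optics, af647):
    """40 noisy frames with ground truth (64x64 px, single dye)."""
    frames, truths = sim.simulate_stack(optics, [af647], 40, 0.1, seed=101)
    return frames, truths


@pytest.fixture(scope="session")
def paired_stack(wide_optics, af647):
    """Noisy + clean stacks from identical truths (for spectral ROI pairs)."""
    frames, clean, truths = sim.simulate_stack(
        wide_optics, [af647], 120, 0.1, seed=202, return_clean=True)
    return frames, clean, truths


@pytest.fixture(scope="session")
def spectral_pairs(paired_stack, wide_optics):
    frames, clean, truths = paired_stack
    cal = sim.true_calibration(wide_optics)
    return sim.make_spectral_training_set(
        frames, clean, truths, cal, mode="labeled", n_pairs=10 ** 9, seed=0)


@pytest.fixture(scope="session")
def tiny_localizer(wide_optics, af647):
    """A briefly trained localizer: usable signal, minutes -> seconds."""
    frames, truths = sim.simulate_stack(wide_optics, [af647], 260, 0.1, seed=7)
    pairs = sim.make_spatial_training_set(
        frames, truths, patch_size=32, upsampling=4, n_pairs=800, seed=1)
    spec = LocalizerSpec(depth=3, base_filters=8, upsampling=4,
                         head_stages=2, l1_weight=0.1)
    return train_localizer(pairs, spec, epochs=3, seed=0)


@pytest.fixture(scope="session")
def tiny_enhancer(spectral_pairs):
    """A briefly trained spectral enhancer (reduced filter count)."""
    train = spectral_pairs[:1500]
    return train_enhancer(train, EnhancerSpec(filters=16), epochs=3, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
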