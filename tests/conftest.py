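import pytest

from myddotrack.config import PipelineConfig, SimulationConfig
from myddotrack.io import ImageStack4D
from myddotrack.simulate import simulate_dataset


@pytest.fixture(scope="session")
def tiny_dataset():
    """A small rendered movie with ground truth, shared across pipeline tests.

    40 frames x 10 z-slices x 96x96 px, one 4-um cell, nucleation burst after
    a 50 s delay, bright puncta (high SNR) with two-step lifetimes.
    """
    cfg = SimulationConfig(
        image_shape=(40, 10, 96, 96),
        cell_radius=4.0,
        nucleation_rate=0.15,
        formation_delay=50.0,
        nucleation_duration=100.0,
        k1=0.01,
        k2=0.04,
        membrane_fraction=0.9,
        photon_amplitude=120.0,
        rng_seed=21,
    )
    stack_arr, events, geometry = simulate_dataset(cfg)
    stack = ImageStack4D(stack_arr, cfg.pixel_size_xy, cfg.z_spacing,
                         cfg.frame_interval)
    return cfg, stack, events, geometry


@pytest.fixture()
def fast_pipeline_config():
    """Pipeline defaults with the (slow) bootstrap turned off."""
    return PipelineConfig(n_bootstrap=0)
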