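import numpy as np
import pytest

from emgsmile import GeneratorConfig, PipelineConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def clean_generator_config():
    """Noise-free, identity-mixing generator: one single-peak smile per block,
    fixed dynamics."""
    means = {k: dict(v) for k, v in GeneratorConfig().type_means.items()}
    for t in means:
        means[t]["n_peaks"] = 1.0
    return GeneratorConfig(
        type_means=means,
        n_producers=1,
        events_per_block=1,
        block_duration_s=30.0,
        mixing_matrix=np.eye(4),
        line_noise_amp=0.0,
        drift_amp=0.0,
        sensor_noise_sd=0.0,
        background_activation=0.0,
        producer_effect_sd=0.0,
        within_producer_gap_fraction=0.0,
        seed=3,
    )


@pytest.fixture
def pipeline_config():
    return PipelineConfig(seed=1)
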