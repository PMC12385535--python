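import numpy as np
import pytest

from skinformer.model import ModelConfig, test_scale_config
from skinformer.synthetic import ClassSpec, DatasetManifest, generate_dataset
from skinformer.train import TrainConfig, train


def four_class_specs(noisy: bool = False):
    colors = [(60, 35, 30), (140, 90, 60), (210, 150, 150), (170, 60, 80)]
    return [
        ClassSpec(i, c, color_jitter=6.0 if noisy else 0.0, irregularity=0.3,
                  texture_noise=15.0 if noisy else 0.0)
        for i, c in enumerate(colors)
    ]


@pytest.fixture(scope="session")
def small_dataset():
    """Zero-noise, color-separable 4-class collection at 64x96."""
    manifest = DatasetManifest(counts=(20, 20, 20, 20), seed=11,
                               split_fractions=(0.7, 0.15, 0.15))
    return generate_dataset(four_class_specs(), manifest)


@pytest.fixture(scope="session")
def small_model_config():
    return test_scale_config(classes_num=4)


@pytest.fixture(scope="session")
def trained_small(small_dataset, small_model_config):
    """A test-scale model trained briefly on the separable 4-class fixture."""
    cfg = TrainConfig(epochs=4, batch_size=10, seed=7, preset="full", augment=False)
    return train(small_model_config, small_dataset, cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
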