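import dataclasses

import numpy as np
import pytest

from mboss import (
    FitConfig,
    GeneratorConfig,
    Instance,
    default_config,
    generate_dataset,
)
from mboss.synthetic import ClassSpec


@pytest.fixture(scope="session")
def default_dataset():
    """The frozen default synthetic benchmark (seed 1)."""
    return generate_dataset(default_config(seed=1))


@pytest.fixture(scope="session")
def small_dataset():
    """Reduced benchmark (3 classes, 4 subjects) for fast end-to-end tests."""
    base = default_config(seed=7)
    return generate_dataset(
        dataclasses.replace(
            base,
            classes=base.classes[:3],
            subjects=4,
            instances_per_class_per_subject=3,
        )
    )


@pytest.fixture(scope="session")
def small_fit_config():
    return FitConfig(seed=7)


def two_class_config(seed: int, noise_std: float = 0.05) -> GeneratorConfig:
    """Two well-separated quasi-periodic classes (1 Hz vs 3 Hz)."""
    classes = (
        ClassSpec("slow", 1.0, (1.0, 0.4), noise_std=noise_std),
        ClassSpec("fast", 3.0, (1.0, 0.4), noise_std=noise_std),
    )
    return GeneratorConfig(classes=classes, subjects=10, seed=seed)


def random_instance(rng: np.random.Generator, n: int = 128, v: int = 3) -> Instance:
    return Instance(segment=rng.normal(size=(n, v)), label="c", subject="s")
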