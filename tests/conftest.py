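import numpy as np
import pytest

from otuflock.synthetic_community import (
    CloudSpec,
    EndemicSpec,
    FlockSpec,
    GeneratorConfig,
    generate_dataset,
)


def small_config(seed: int = 0, **overrides) -> GeneratorConfig:
    """A fast, fully structured generator config used across the suite:
    2 planted flocks, 1 intragenomic cloud, 3 endemics, background OTUs."""
    kwargs = dict(
        n_references=5,
        n_background_otus=8,
        flocks=[FlockSpec(n_tips=4, target_divergence=0.015),
                FlockSpec(n_tips=5, target_divergence=0.02)],
        clouds=[CloudSpec(n_satellites=5, identity_range=(0.95, 0.99),
                          dominant_reads=6000, satellite_read_cap=50)],
        endemic_otus=EndemicSpec(n=3, distance_range=(0.12, 0.20)),
        n_samples=4,
        depth_range=(2500, 4000),
        seed=seed,
    )
    kwargs.update(overrides)
    return GeneratorConfig(**kwargs)


@pytest.fixture(scope="session")
def small_dataset():
    return generate_dataset(small_config(seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
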