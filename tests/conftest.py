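import numpy as np
import pytest
from hypothesis import settings

from ctvolumetry import ExperimentConfig, make_fixture
from ctvolumetry.acquisition import DEFAULT_KERNELS

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


def small_config(seed=0, **overrides):
    """A reduced experiment grid that runs in seconds."""
    base = dict(
        diameters_mm=(6.35, 9.525, 12.7),
        n_replicates=2,
        container_mm=(80.0, 80.0, 100.0),
        fovs_cm=(20.0,),
        kernels={"standard": DEFAULT_KERNELS["standard"],
                 "lung": DEFAULT_KERNELS["lung"]},
        thickness_factors=(1, 2),
        matrix=160,
        supersample=4,
        threshold=93.0,
        exclude_smallest=True,
        seed=seed,
    )
    base.update(overrides)
    return ExperimentConfig(**base)


@pytest.fixture(scope="session")
def tiny_fixture():
    """Three well-separated spheres on a coarse 1 mm grid."""
    return make_fixture("tiny", seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
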