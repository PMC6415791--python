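import numpy as np
import pytest

from pasture import (
    GrowthParameters,
    SceneSpec,
    generate_scene,
    generate_weather,
    load_species_params,
)


@pytest.fixture(scope="session")
def fescue():
    return load_species_params("fescue")


@pytest.fixture(scope="session")
def ryegrass():
    return load_species_params("ryegrass")


@pytest.fixture(scope="session")
def growth_params():
    return GrowthParameters()


@pytest.fixture(scope="session")
def constant_weather():
    """30 days at tmean 20 degC, srad 20, no rain: 16 degC d per day at t_base 4."""
    return generate_weather(30, "constant", seed=0)


@pytest.fixture(scope="session")
def small_scene():
    """Noiseless 4-paddock scene at 2 m pixels with known truth."""
    spec = SceneSpec(n_paddocks=4, pixel_size=2.0, noise_cv=0.0, seed=11)
    scene, pmap, truth = generate_scene(spec)
    return spec, scene, pmap, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
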