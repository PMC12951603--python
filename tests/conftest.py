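import numpy as np
import pytest

from jawstrength import GeneratorParams, StudyConfig, generate_study


@pytest.fixture
def rng():
    return np.random.default_rng(20230915)


@pytest.fixture(scope="session")
def small_params():
    """A reduced four-islet study for fast end-to-end tests."""
    return GeneratorParams(
        populations=("A", "B", "C", "D"),
        n_field=(14, 14, 14, 14),
        n_field_male=(7, 7, 7, 7),
        n_alcohol=(6, 6, 6, 6),
        n_alcohol_male=(3, 3, 3, 3),
        collection_years=(1940, 1955, 1968, 1979),
        seed=7,
    )


@pytest.fixture(scope="session")
def small_bundle(small_params):
    return generate_study(small_params)


@pytest.fixture(scope="session")
def default_bundle():
    """The full eight-islet study at the default sample sizes."""
    return generate_study(GeneratorParams(seed=11))


@pytest.fixture
def fast_config(tmp_path):
    return StudyConfig(seed=3, n_permutations=199, out_dir=tmp_path / "out")
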