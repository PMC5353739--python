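from __future__ import annotations

import numpy as np
import pytest

from gliadin_atlas.epitopes import default_panel
from gliadin_atlas.profiles import default_profiles, profile_by_type
from gliadin_atlas.synthetic import GeneratorConfig, make_corpus


@pytest.fixture(scope="session")
def profiles():
    return default_profiles()


@pytest.fixture(scope="session")
def alpha_profile(profiles):
    return profile_by_type(profiles, "alpha")


@pytest.fixture(scope="session")
def gamma_profile(profiles):
    return profile_by_type(profiles, "gamma")


@pytest.fixture(scope="session")
def omega_profile(profiles):
    return profile_by_type(profiles, "omega")


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def corpus():
    """The default study-design corpus (seed 7), shared across the suite."""
    return make_corpus(GeneratorConfig(seed=7))


@pytest.fixture(scope="session")
def corpus_truth(corpus):
    return corpus.truth.set_index("gene_id")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
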