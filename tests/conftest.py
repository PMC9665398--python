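import numpy as np
import pytest

import avchoice as av
from avchoice.io import choices_to_frame


@pytest.fixture(scope="session")
def design():
    return av.generate_choice_design()


@pytest.fixture(scope="session")
def small_survey():
    """A 12-participant UK-preset survey shared across read-only tests."""
    spec = av.load_preset("uk-paper", n_participants=12)
    return spec, av.simulate_survey(spec, seed=42)


@pytest.fixture(scope="session")
def small_fit(small_survey):
    """A quick fit of the small survey (for plumbing tests, not recovery)."""
    _, tables = small_survey
    model = av.HierarchicalProbitChoiceModel(
        n_chains=2, n_samples=1200, n_burnin=300, seed=7
    )
    model.fit(choices_to_frame(tables["scenarios"], tables["choices"]))
    return model


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
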