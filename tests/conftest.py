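import numpy as np
import pytest

from predtend.pipeline import make_fixtures
from predtend.preprocessing import preprocess


@pytest.fixture(scope="session")
def fixtures():
    """Miniature deterministic cohort: 3 subjects, 8 channels, 2x100 trials."""
    return make_fixtures(seed=7)


@pytest.fixture(scope="session")
def fixture_epochs(fixtures):
    """Preprocessed epochs of the highest-tendency fixture subject."""
    rec = fixtures["subjects"][2]["recording"]
    return preprocess(rec)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
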