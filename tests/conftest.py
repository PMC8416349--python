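import numpy as np
import pytest

from gaitnarx.narx import NarxConfig, NarxWeights, init_weights
from gaitnarx.sigproc import preprocess_session
from gaitnarx.synthetic import (
    VariabilityModel,
    default_templates,
    generate_session,
    zero_variability,
)


@pytest.fixture(scope="session")
def templates():
    return default_templates()


@pytest.fixture(scope="session")
def lw_session(templates):
    """11 preprocessed level-walking trials (cheap single-condition session)."""
    raw = generate_session(
        {"LW": templates["LW"]}, VariabilityModel(seed=11), 11
    )
    return preprocess_session(raw)


@pytest.fixture(scope="session")
def full_session(templates):
    """Default benchmark session: 11 trials x 3 conditions, coupling 0.6."""
    raw = generate_session(default_templates(), VariabilityModel(seed=42), 11)
    return preprocess_session(raw)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_weights(config: NarxConfig, seed=0, scale=0.5) -> NarxWeights:
    """Dense random weights for oracle tests (wider than the init scheme)."""
    r = np.random.default_rng(seed)
    n, d = config.n_hidden, config.d
    return NarxWeights(
        a=r.normal(0, scale, (n, 2, d + 1)),
        c=r.normal(0, scale, (n, 2, d)),
        w=r.normal(0, scale, (2, n)),
        b1=r.normal(0, scale, n),
        b2=r.normal(0, scale, 2),
    )
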