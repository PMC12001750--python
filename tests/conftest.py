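import numpy as np
import pytest

from fragsignal import simulate


SMALL = dict(
    n_arms=4,
    amplicons_per_arm=40,
    n_controls=60,
    n_cancers=40,
    depth_mean=100.0,
)


@pytest.fixture(scope="session")
def small_cohort():
    """A small labelled cohort shared by unit tests (fast to generate)."""
    cfg = simulate.SimConfig(**SMALL)
    return simulate.gen_cohort(cfg, seed=101)


@pytest.fixture(scope="session")
def small_config():
    return simulate.SimConfig(**SMALL)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
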