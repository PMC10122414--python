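import pytest

from erwbox import World
from erwbox.fixtures import make_fixtures
from erwbox.pipeline import run_reference_experiments

REFERENCE_SEED = 1


@pytest.fixture(scope="session")
def world():
    return World()


@pytest.fixture(scope="session")
def spun(world):
    """Preindustrial restart state (two-stage spinup), shared session-wide."""
    return world.spinup()


@pytest.fixture(scope="session")
def bundle():
    return make_fixtures(seed=0)


@pytest.fixture(scope="session")
def reference():
    """The full reference analysis: filtered ensemble, three scenarios,
    baseline + ERW branches, headline metrics. Expensive (minutes); shared
    by every acceptance-level test."""
    return run_reference_experiments(REFERENCE_SEED, n_prior=30000, n_coupled=130,
                                     keep_ledgers=True)
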