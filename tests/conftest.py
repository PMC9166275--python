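import pytest

import iguanapop as ig
from iguanapop import datasets


@pytest.fixture(scope="session")
def surveys():
    return datasets.load_surveys()


@pytest.fixture(scope="session")
def harvest():
    return datasets.load_harvest()


@pytest.fixture(scope="session")
def params():
    return ig.GrowthParams(K=1_378_259.0, r_max=1.323, sigma_proc=0.0)


@pytest.fixture(scope="session")
def quick_fit(surveys, harvest):
    """A short packaged-data fit for structural/smoke tests (not summaries)."""
    return ig.run_mcmc(
        surveys, harvest, n_chains=2, n_iter=4_000, n_burn=2_000, seed=11
    )


@pytest.fixture(scope="session")
def packaged_fit(surveys, harvest):
    """The full packaged-data fit at study settings, shared across tests."""
    return ig.run_mcmc(
        surveys, harvest, n_chains=4, n_iter=50_000, n_burn=25_000, seed=20
    )
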