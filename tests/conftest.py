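import numpy as np
import pytest

import mcmgene as m
from mcmgene.chain import ChainKind
from mcmgene.doseresponse import chain_seed

PIPELINE_SEED = 1


@pytest.fixture(scope="session")
def dox_grid():
    return m.default_dox_grid()


@pytest.fixture(scope="session")
def reference_curves(dox_grid):
    return m.ReferenceCurves().observed_curves(dox_grid)


@pytest.fixture(scope="session")
def estimated_models(reference_curves):
    """Estimated switching models for all three chains (seed 1)."""
    return {
        chain: m.estimate(reference_curves, chain,
                          seed=chain_seed(PIPELINE_SEED, chain))
        for chain in ChainKind
    }


@pytest.fixture(scope="session")
def full_prediction():
    """The complete estimate -> simulate -> fit pipeline at study scale
    (10,000 cells, 34 doses, 200 cycles), shared across acceptance tests."""
    report, artifacts = m.run_prediction(seed=PIPELINE_SEED)
    return report, artifacts


@pytest.fixture()
def rng():
    return np.random.default_rng(20260927)
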