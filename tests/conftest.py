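"""Shared fixtures: one desk-scale gingiva pipeline reused across the suite.

The heavy objects (white-MC path tables, the Rd lookup, the simulated
corpus and the trained inverse model) are session-scoped so transport runs
and network training happen once.
"""

import numpy as np
import pytest

from hsiq.ann import NetworkConfig, train
from hsiq.chromophores import ChromophoreLibrary
from hsiq.dataset import default_ranges, fit_scalers, make_band_grid, simulate_corpus
from hsiq.mc import WhiteMonteCarloEngine, build_lookup
from hsiq.tissue import gingiva_model, skin_model

PIPELINE_SEED = 1
CORPUS_SIZE = 4700  # 64/16/20 split -> 3008 training spectra (desk profile)


@pytest.fixture(scope="session")
def band_grid():
    return make_band_grid()


@pytest.fixture(scope="session")
def library():
    return ChromophoreLibrary.default()


@pytest.fixture(scope="session")
def gingiva():
    return gingiva_model()


@pytest.fixture(scope="session")
def skin():
    return skin_model()


@pytest.fixture(scope="session")
def gingiva_engine(band_grid):
    return WhiteMonteCarloEngine(
        "gingiva", band_grid, n_musp_nodes=32, n_photons=10_000,
        seed=PIPELINE_SEED,
    )


@pytest.fixture(scope="session")
def gingiva_lookup(gingiva_engine):
    return build_lookup(gingiva_engine)


@pytest.fixture(scope="session")
def gingiva_corpus(gingiva_lookup):
    return simulate_corpus(
        gingiva_lookup, default_ranges(), n=CORPUS_SIZE, seed=PIPELINE_SEED,
        tissue="gingiva",
    )


@pytest.fixture(scope="session")
def gingiva_scalers(gingiva_corpus):
    return fit_scalers(gingiva_corpus)


@pytest.fixture(scope="session")
def gingiva_ann(gingiva_corpus, gingiva_scalers):
    config = NetworkConfig(seed=PIPELINE_SEED, max_epochs=300, patience=25)
    return train(gingiva_corpus, gingiva_scalers, config)
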