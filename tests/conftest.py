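import numpy as np
import pytest

from evometa import ModelParams, PatchState, make_fixture


@pytest.fixture
def params():
    return ModelParams()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def monomorphic(params, rng):
    state, p = make_fixture("monomorphic", rng, params)
    return state, p


@pytest.fixture
def two_species(params, rng):
    state, p = make_fixture("two-species-per-patch", rng, params)
    return state, p


def random_patch(rng, n_lineages, x_opt=0.0, index=0, lid_start=0):
    """A random small patch for oracle trials."""
    return PatchState(
        x_opt,
        x=rng.uniform(-2, 2, n_lineages),
        N=rng.uniform(1, 5000, n_lineages),
        species_id=rng.integers(1, 4, n_lineages),
        lineage_id=np.arange(lid_start, lid_start + n_lineages),
        born=np.zeros(n_lineages, dtype=np.int64),
        index=index,
    )
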