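import numpy as np
import pytest

from loopbind import synth
from loopbind.model_core import AtomicModel


@pytest.fixture(scope="session")
def toy():
    """One toy complex shared by the whole suite (truth, start, partition, ...)."""
    truth, start, partition, restraints, manifest = synth.make_toy_complex(
        synth.ToyComplexSpec(seed=0)
    )
    return {"truth": truth, "start": start, "partition": partition,
            "restraints": restraints, "manifest": manifest}


def make_model(coords, names=None, elements=None, res_ids=None, res_names=None,
               chains=None):
    """Small hand-built model helper for unit tests."""
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    return AtomicModel(
        serial=np.arange(1, n + 1),
        name=np.array(names if names is not None else [f"X{i}" for i in range(n)]),
        element=np.array(elements if elements is not None else ["C"] * n),
        res_id=np.array(res_ids if res_ids is not None else np.arange(1, n + 1)),
        res_name=np.array(res_names if res_names is not None else ["ALA"] * n),
        chain_id=np.array(chains if chains is not None else ["A"] * n),
        coord=coords,
    )


@pytest.fixture
def random_carbon_model():
    def _make(n=50, seed=0, box=20.0):
        rng = np.random.default_rng(seed)
        return make_model(rng.uniform(-box, box, (n, 3)))
    return _make
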