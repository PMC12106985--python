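import numpy as np
import pytest

from fgmspatial.design import ModelSpec
from fgmspatial.model import BayesSpatialLogit
from fgmspatial.scenarios import lattice_study, recovery_dataset


@pytest.fixture(scope="session")
def lattice():
    """Standard 3x4 lattice geography (graph, zones, ICAR structure)."""
    return lattice_study()


@pytest.fixture(scope="session")
def fitted_m2():
    """One recovery replicate with its m2 fit, shared across tests."""
    records, params, graph, structure = recovery_dataset(seed=11)
    model = BayesSpatialLogit.from_dataframe(
        records, ModelSpec("m2", "individual"), graph=graph
    )
    results = model.fit(iterations=1200, burn_in=400, seed=12)
    return records, params, model, results


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
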