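import numpy as np
import pytest

from exprmtl.data import stratified_split
from exprmtl.model import MultiTaskLogit
from exprmtl.simulate import SimulationSpec, simulate


@pytest.fixture(scope="session")
def standard_sim():
    """The standard synthetic study: 6 classes x 50 samples, 300 genes,
    10 signal genes per class shifted by 2 noise SDs."""
    return simulate(SimulationSpec())


@pytest.fixture(scope="session")
def standard_split(standard_sim):
    return stratified_split(standard_sim.dataset, 0.2, seed=1)


@pytest.fixture(scope="session")
def fitted_results(standard_split):
    """Model fitted on the standard training partition at the reference
    penalties (lambda1=1e-4, lambda2=1e-5)."""
    return MultiTaskLogit.from_dataset(standard_split.train).fit(1e-4, 1e-5)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
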