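import numpy as np
import pytest

from aucselect import BiomarkerData, SimulationScenario, generate_dataset


@pytest.fixture
def toy_data():
    """Controls {1, 3}, cases {2, 4} on a single marker: AUC-hat = 0.75."""
    return BiomarkerData([[1], [3], [2], [4]], [0, 0, 1, 1])


@pytest.fixture
def correlated_data():
    """Moderate-size correlated 3-marker dataset away from any boundary."""
    scen = SimulationScenario(
        d=3, N=60, rho=0.6, true_auc=(0.65, 0.75, 0.7), auc0=0.5, seed=0
    )
    return generate_dataset(scen, np.random.default_rng(42))


def random_tied_dataset(rng, n0=None, n1=None, d=None, n_levels=6):
    """Small integer-valued dataset with plenty of ties, for oracle checks."""
    n0 = n0 or rng.integers(2, 10)
    n1 = n1 or rng.integers(2, 10)
    d = d or rng.integers(1, 4)
    values = rng.integers(0, n_levels, size=(n0 + n1, d)).astype(float)
    status = np.concatenate([np.zeros(n0, dtype=int), np.ones(n1, dtype=int)])
    return BiomarkerData(values, status)
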