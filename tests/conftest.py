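import numpy as np
import pytest

from crterp.layout import ElectrodeLayout, biosemi128_layout
from crterp.simulate import default_ground_truth, simulate_erp_dataset


@pytest.fixture(scope="session")
def layout():
    return biosemi128_layout()


@pytest.fixture(scope="session")
def toy_layout():
    """20 electrodes spread over a sphere (small instances, oracles)."""
    rng = np.random.default_rng(42)
    pos = rng.normal(size=(20, 3))
    pos /= np.linalg.norm(pos, axis=1, keepdims=True)
    return ElectrodeLayout([f"e{i}" for i in range(20)], pos)


@pytest.fixture(scope="session")
def study_erps(layout):
    """One canonical synthetic study: 20 subjects, default ground truth."""
    truth = default_ground_truth(layout, seed=0)
    erps, info = simulate_erp_dataset(truth, n_subjects=20, layout=layout, seed=1)
    return truth, erps, info


@pytest.fixture(scope="session")
def leadfield(layout):
    from crterp.headmodel import make_toy_leadfield

    return make_toy_leadfield(200, layout, seed=0)
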