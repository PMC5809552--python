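import numpy as np
import pytest

from medfx.model import MediationDataset, SimulationCondition
from medfx.simulate import generate_dataset


@pytest.fixture(scope="session")
def single_dataset():
    """n=200 single-mediator dataset at medium paths."""
    cond = SimulationCondition(n=200, paths={"a": 0.39, "b": 0.39, "c_prime": 0.39})
    return generate_dataset(cond, seed=11)


@pytest.fixture(scope="session")
def two_dataset():
    cond = SimulationCondition(
        n=200, paths={"a1": 0.314, "b1": 0.314, "a2": 0.101, "b2": 0.101, "c_prime": 0.4}
    )
    return generate_dataset(cond, seed=12)


@pytest.fixture
def handcrafted_4pt():
    """4-point dataset whose normal equations were solved by hand.

    x = [0,1,2,3], m = [1,0,2,1], y = [0,1,1,2]:
    Sxx=5, Sxm=1, Smm=2, Sxy=3, Smy=0 =>
    a = 1/5, c = 3/5, [c', b] = [[5,1],[1,2]]^-1 [3,0] = [2/3, -1/3].
    """
    return MediationDataset(
        x=np.array([0.0, 1, 2, 3]),
        mediators=(np.array([1.0, 0, 2, 1]),),
        y=np.array([0.0, 1, 1, 2]),
    )
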