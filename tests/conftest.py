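import numpy as np
import pandas as pd
import pytest

from methylcaps.core import CapsuleMap, MethylationArray
from methylcaps.simulate import SimulationSpec, simulate_dataset


@pytest.fixture
def small_cmap() -> CapsuleMap:
    return CapsuleMap(
        {"A": ["cg1", "cg2", "cg3"], "B": ["cg4", "cg5"], "C": ["cg2", "cg6"]}
    )


@pytest.fixture
def toy_array() -> MethylationArray:
    rng = np.random.default_rng(7)
    beta = pd.DataFrame(
        rng.random((6, 6)),
        index=[f"s{i}" for i in range(6)],
        columns=[f"cg{i + 1}" for i in range(6)],
    )
    pheno = pd.DataFrame({"label": ["x", "x", "x", "y", "y", "y"]}, index=beta.index)
    return MethylationArray(beta, pheno)


@pytest.fixture(scope="session")
def default_sim():
    """The standard synthetic classification setting (4 classes, 20 capsules
    of 10 CpGs, 5 signal, effect size 0.3, 150 samples/class)."""
    return simulate_dataset(SimulationSpec(seed=1))
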