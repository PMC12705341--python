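import numpy as np
import pandas as pd
import pytest

from npcrisk.deconv import DeconvReference
from npcrisk.simulate import SimulationConfig, simulate_cohorts


@pytest.fixture(scope="session")
def study():
    """Study-design simulation: three cohorts (39/38, 13/17, 23/47) with
    15 up / 14 down planted markers, plus its ground truth."""
    cohorts, truth = simulate_cohorts(SimulationConfig(seed=11, n_genes=1200))
    return cohorts, truth


@pytest.fixture(scope="session")
def small_ref():
    """A random full-column-rank 4-type deconvolution reference."""
    rng = np.random.default_rng(42)
    genes = [f"g{i:03d}" for i in range(60)]
    types = ["tumour", "fibroblast", "t_cell", "plasma_b"]
    mean = pd.DataFrame(rng.uniform(1.0, 50.0, (60, 4)), index=genes, columns=types)
    var = pd.DataFrame(rng.uniform(0.5, 5.0, (60, 4)), index=genes, columns=types)
    return DeconvReference(mean, var)
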