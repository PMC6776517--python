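import numpy as np
import pandas as pd
import pytest

import bymmap as bm
from bymmap import cohort, mcmc


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def lattice33():
    return bm.make_lattice(3, 3)


@pytest.fixture(scope="session")
def synth_dataset():
    """Default-condition synthetic cohort on a 10x10 lattice."""
    return bm.simulate_counts(bm.SimulationConfig(seed=42))


@pytest.fixture(scope="session")
def fitted_convolution(synth_dataset):
    """One converged convolution-model fit shared by summary/diagnostic tests."""
    table = cohort.expected_counts(synth_dataset.stratum_table)
    out = bm.run_mcmc(
        bm.ModelSpec(effects="both"),
        table,
        synth_dataset.adjacency,
        chains=2,
        burn_in=2000,
        iterations=5000,
        max_batches=3,
        seed=7,
    )
    return synth_dataset, table, out


def tiny_table(n_areas=5, cases=(1, 0, 2, 0, 1)):
    """Minimal one-stratum-per-area table for sampler unit tests."""
    rows = []
    for i in range(n_areas):
        rows.append(
            {
                "area_id": f"a{i}",
                "age_group": "le60",
                "sex": "female",
                "participants": 100,
                "cases": cases[i % len(cases)],
                "expected": 1.0,
            }
        )
    return pd.DataFrame(rows)


@pytest.fixture
def tiny_data():
    table = tiny_table()
    spec = mcmc.ModelSpec(effects="unstructured", include_age=False, include_sex=False)
    return mcmc.ModelData(table, spec), table
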