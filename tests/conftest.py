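import numpy as np
import pandas as pd
import pytest

from binet import booleannet, network, stepminer, synthetic


@pytest.fixture(scope="session")
def planted():
    """Default planted 3-cluster chain dataset (seed 1)."""
    return synthetic.generate_dataset(synthetic.SimConfig(seed=1))


@pytest.fixture(scope="session")
def planted_pipeline(planted):
    """Thresholds, states, kept genes, and records for the planted dataset."""
    m = planted.matrix
    thresholds = stepminer.threshold_matrix(m)
    states = stepminer.discretize(m, thresholds)
    kept = stepminer.filter_genes(m, states)
    records = booleannet.discover_implications(states.loc[kept])
    return {
        "matrix": m,
        "thresholds": thresholds,
        "states": states,
        "kept": kept,
        "records": records,
    }


@pytest.fixture(scope="session")
def planted_bin(planted_pipeline):
    return network.BIN.from_records(
        planted_pipeline["records"], genes=planted_pipeline["kept"]
    )


def make_matrix(rows, genes=None, samples=None):
    arr = np.asarray(rows, dtype=float)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    return pd.DataFrame(arr, index=genes, columns=samples)
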