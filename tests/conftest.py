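import numpy as np
import pandas as pd
import pytest

from mhcprofiler.cohort import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Two cancer types, three subtypes each, modest gene panel."""
    config = CohortConfig(
        n_cancer_types=2,
        subtypes_per_type=3,
        samples_per_subtype=20,
        n_normal_per_type=10,
        n_genes_background=120,
        panel_spec={"CAG": 20, "immunoinhibitor": 8, "MHC": 12, "other": 0},
        seed=7,
    )
    return generate_cohort(config)


@pytest.fixture
def rng():
    return np.random.default_rng(123)


def grouped_dataset(rng, sizes, n_vars=3, shift=0.0):
    """Random grouped data: variable-by-sample frame plus group labels."""
    labels, cols = [], []
    for gi, n in enumerate(sizes):
        labels += [f"g{gi}"] * n
    x = rng.normal(0.0, 1.0, size=(n_vars, sum(sizes)))
    offset = 0
    for gi, n in enumerate(sizes):
        x[:, offset:offset + n] += gi * shift
        offset += n
    values = pd.DataFrame(x, index=[f"v{i}" for i in range(n_vars)],
                          columns=[f"s{i}" for i in range(sum(sizes))])
    return values, pd.Series(labels, index=values.columns)
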