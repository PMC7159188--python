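import numpy as np
import pandas as pd
import pytest

from thymonet import RunConfig, simulate_dataset
from thymonet.types import ExpressionMatrix, SampleMetadata


@pytest.fixture(scope="session")
def default_sim():
    """Full-size default synthetic dataset (1500 genes x 50 samples)."""
    return simulate_dataset(seed=0)


@pytest.fixture(scope="session")
def small_sim():
    """Small dataset (3 modules of 60 genes, one trait-linked) for fast runs."""
    return simulate_dataset(
        seed=0, n_genes=400, module_sizes=(60, 60, 60),
        trait_effects=((2, "E", 0.45),), mirna_spec=(60, 8, 5.3),
        n_mirna_edges=6, tf_spec=(10, 4))


@pytest.fixture(scope="session")
def config():
    return RunConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_matrix(values, features=None, samples=None) -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    features = features or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=features, columns=samples))


def make_meta(groups: dict[str, list[str]]) -> SampleMetadata:
    rows = []
    for g, samples in groups.items():
        for i, s in enumerate(samples):
            rows.append({"sample_id": s, "age_group": g,
                         "gender": "F" if i % 2 == 0 else "M"})
    return SampleMetadata(pd.DataFrame(rows).set_index("sample_id"))
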