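import numpy as np
import pandas as pd
import pytest

import pannetsub as ps


@pytest.fixture(scope="session")
def small_cohort():
    """A compact synthetic cohort shared by read-only tests."""
    cfg = ps.CohortConfig(
        n_probes=3000,
        n_genes=1500,
        n_per_group={"alpha_like": 15, "ADM1": 12, "ADM2": 12, "ADM3": 10,
                     "ADM4": 2},
        n_dmp=300,
        n_de_per_subtype=80,
        n_coupled=20,
    )
    return ps.simulate_cohort(cfg, seed=11)


@pytest.fixture(scope="session")
def toy_manifest():
    genome = ps.default_genome()
    return genome, ps.make_manifest(genome, 2000, seed=5)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def group_blobs(n_features=60, n_per_group=(8, 8), signal=4.0, seed=0):
    """Well-separated groups sharing a per-group feature signature.

    Correlation-based clustering needs within-group shared structure, so
    each group gets its own feature signature plus unit noise. Returns a
    features x samples frame with columns G{g}S{i}.
    """
    rng = np.random.default_rng(seed)
    blocks, cols = [], []
    for g, n in enumerate(n_per_group):
        signature = rng.normal(0.0, signal, size=(n_features, 1))
        blocks.append(signature + rng.normal(0.0, 1.0, size=(n_features, n)))
        cols.extend(f"G{g}S{i}" for i in range(n))
    return pd.DataFrame(np.hstack(blocks), columns=cols)
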