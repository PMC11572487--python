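import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from ibspred.synthetic import SyntheticConfig, generate_pipeline_fixture


@pytest.fixture(scope="session")
def small_fixture():
    """Shared 20-protein strong-signal fixture (records + embeddings)."""
    config = SyntheticConfig(n_proteins=20, length_range=(60, 100), seed=11)
    records, embeddings = generate_pipeline_fixture(config)
    return config, records, embeddings


@pytest.fixture
def separable_rows():
    """Two well-separated Gaussian clusters with ~10% positives."""
    rng = np.random.default_rng(5)
    n_neg, n_pos, d = 180, 20, 8
    X = np.vstack(
        [
            rng.standard_normal((n_neg, d)),
            rng.standard_normal((n_pos, d)) + 12.0,
        ]
    ).astype(np.float32)
    y = np.concatenate([np.zeros(n_neg, dtype=int), np.ones(n_pos, dtype=int)])
    perm = rng.permutation(len(y))
    return X[perm], y[perm]
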