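import numpy as np
import pandas as pd
import pytest

from schybrid import (CellTable, ProbMatrix, SimConfig, simulate_fit_predict)


@pytest.fixture(scope="session")
def default_run():
    """One moderately sized end-to-end run shared across read-only tests."""
    return simulate_fit_predict(SimConfig(n_cells=1500, seed=7))


@pytest.fixture()
def tiny_prob():
    probs = np.array([
        [0.5, 0.5, 0.0],
        [0.9, 0.1, 0.0],
        [0.2, 0.6, 0.2],
        [0.0, 0.0, 1.0],
    ])
    return ProbMatrix(probs, [f"c{i}" for i in range(4)], ["A", "B", "C"])


@pytest.fixture()
def tiny_cells():
    return CellTable(pd.DataFrame({
        "cell_id": [f"c{i}" for i in range(4)],
        "reference_label": ["A", "A", "B", "C"],
        "group": ["g1", "g1", "g1", "g2"],
    }))


def random_prob_matrix(rng, n_cells=200, n_classes=5):
    """Uniform draws projected onto the simplex by normalization."""
    raw = rng.random((n_cells, n_classes)) + 1e-9
    probs = raw / raw.sum(axis=1, keepdims=True)
    cells = np.array([f"r{i}" for i in range(n_cells)], dtype=object)
    labels = np.array([f"T{j}" for j in range(n_classes)], dtype=object)
    return ProbMatrix(probs, cells, labels)
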