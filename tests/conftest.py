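import numpy as np
import pandas as pd
import pytest

from aesig.synthetic import SyntheticConfig, gen_ae_counts
from aesig.types import SimilarityNetwork


@pytest.fixture(scope="session")
def small_counts():
    """134 x 15 count matrix matching the desk-scale cohort layout."""
    cfg = SyntheticConfig(seed=11, n_drugs=15, n_aes=134, k_true=4,
                          count_scale=650.0)
    X, truth = gen_ae_counts(cfg)
    return X, truth


@pytest.fixture(scope="session")
def recovery_counts():
    """Well-powered count matrix for signature recovery checks."""
    cfg = SyntheticConfig(seed=7, n_drugs=40, n_aes=150, k_true=4,
                          count_scale=500.0)
    return gen_ae_counts(cfg)


@pytest.fixture
def tiny_net():
    ids = ["a", "b", "c"]
    M = np.array([[1.0, 0.4, 0.6], [0.4, 1.0, 0.2], [0.6, 0.2, 1.0]])
    return SimilarityNetwork(ids=ids, matrix=M, source="test", stage="first")


def hungarian_accuracy(true_labels: pd.Series, est_labels: pd.Series) -> float:
    """Cluster agreement after optimal label matching."""
    from scipy.optimize import linear_sum_assignment
    drugs = [d for d in est_labels.index]
    k1 = int(true_labels.max())
    k2 = int(est_labels.max())
    C = np.zeros((k1, k2))
    for d in drugs:
        C[int(true_labels[d]) - 1, int(est_labels[d]) - 1] += 1
    r, c = linear_sum_assignment(-C)
    return float(C[r, c].sum() / len(drugs))


def matched_column_cosines(true_W: pd.DataFrame, est_W: pd.DataFrame):
    """Cosines of Hungarian-matched signature columns."""
    from scipy.optimize import linear_sum_assignment
    A = true_W.to_numpy()
    B = est_W.to_numpy()
    A = A / np.linalg.norm(A, axis=0)
    B = B / np.linalg.norm(B, axis=0)
    C = A.T @ B
    r, c = linear_sum_assignment(-C)
    return C[r, c]
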