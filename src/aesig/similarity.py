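"""First-stage drug-drug similarity networks from raw source tables.

One metric per data modality, all mapping into [0, 1]:

* AE report profiles: cosine similarity of per-drug relative AE frequencies
* binary fingerprints (chemical structure, bioassay): Tanimoto / Jaccard
* expression profiles: Spearman rank correlation shifted to [0, 1]
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .types import SimilarityNetwork, check_counts


def _finalize(matrix: np.ndarray, ids, source: str) -> SimilarityNetwork:
    matrix = np.clip((matrix + matrix.T) / 2, 0.0, 1.0)
    np.fill_diagonal(matrix, 1.0)
    return SimilarityNetwork(ids=list(ids), matrix=matrix,
                             source=source, stage="first")


def ae_profile_similarity(counts: pd.DataFrame) -> SimilarityNetwork:
    """Cosine similarity between drugs' relative AE frequency vectors."""
    check_counts(counts)
    totals = counts.sum(axis=0)
    zero = totals.index[totals == 0]
    if len(zero):
        raise ValueError(f"drug(s) with zero total report count: {list(zero)}")
    freq = counts.to_numpy(dtype=float) / totals.to_numpy()
    norms = np.linalg.norm(freq, axis=0)
    sim = (freq.T @ freq) / np.outer(norms, norms)
    return _finalize(sim, counts.columns, "ae")


def fingerprint_similarity(features: pd.DataFrame,
                           source: str = "chemical") -> SimilarityNetwork:
    """Tanimoto similarity on binary fingerprint rows (drugs x bits).

    Drugs whose fingerprint is all-zero get similarity 0 to every other
    drug (and 1 to themselves), keeping the matrix total.
    """
    B = features.to_numpy()
    if not np.isin(B, (0, 1)).all():
        raise ValueError("fingerprints must be binary (0/1)")
    B = B.astype(float)
    inter = B @ B.T
    on = B.sum(axis=1)
    union = on[:, None] + on[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / np.where(union > 0, union, 1), 0.0)
    return _finalize(sim, features.index, source)


def expression_similarity(profile: pd.DataFrame,
                          source: str = "expression") -> SimilarityNetwork:
    """Shifted Spearman correlation between drug expression columns."""
    if profile.shape[0] < 3:
        raise ValueError("need at least three genes for rank correlation")
    arr = profile.to_numpy(dtype=float)
    const = profile.columns[arr.std(axis=0) == 0]
    if len(const):
        raise ValueError(
            f"constant expression column(s): {list(const)} "
            "(rank correlation undefined)")
    rho = stats.spearmanr(arr, axis=0).statistic
    if np.ndim(rho) == 0:  # scipy collapses the 2-column case to a scalar
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    return _finalize((rho + 1.0) / 2.0, profile.columns, source)
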