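"""AE-signature extraction by non-negative matrix factorization.

The drug-by-AE report count matrix X (p AEs x n drugs) is approximated by
``X ~ W H`` where each column of W is an AE signature (a probability
distribution over AEs after column normalization) and each column of H
holds a drug's loadings on the signatures.  Because X holds report counts,
the default objective is the generalized Kullback-Leibler divergence
``D(X || WH)`` minimized by Lee-Seung multiplicative updates, restarted
from many seeded random initializations; a Frobenius option is available.

The signature count k is selected by consensus-clustering stability:
repeated factorizations, a drug-pair co-clustering consensus matrix, and
the cophenetic correlation of its average-linkage dendrogram.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import squareform

from .types import ClusterAssignment, check_counts

_EPS = 1e-12


@dataclass
class SignatureModel:
    """Best-of-restarts factorization ``X ~ W H``.

    W is column-stochastic (each signature sums to 1 over AEs) with the
    inverse scaling folded into H so that the product W H is unchanged.
    ``history`` records the objective after every update iteration of the
    winning restart (monotonically non-increasing for multiplicative
    updates).
    """

    W: pd.DataFrame
    H: pd.DataFrame
    k: int
    objective: float
    n_init: int
    seed: object
    loss: str = "kl"
    history: np.ndarray = field(default_factory=lambda: np.array([]))
    restart_objectives: np.ndarray = field(default_factory=lambda: np.array([]))


@dataclass
class StabilityReport:
    """Consensus stability of candidate signature counts."""

    k_values: list
    consensus: dict
    cophenetic: dict
    selected_k: int


def _kl_objective(X, WH):
    mask = X > 0
    out = np.sum(WH) - np.sum(X[mask])
    out += np.sum(X[mask] * np.log(X[mask] / WH[mask]))
    return float(out)


def _factorize_once(X, k, rng, max_iter, tol, loss):
    p, n = X.shape
    scale = np.sqrt(X.mean() / k)
    W = scale * rng.uniform(_EPS, 1.0, size=(p, k))
    H = scale * rng.uniform(_EPS, 1.0, size=(k, n))
    history = []
    prev = None
    for _ in range(max_iter):
        if loss == "kl":
            WH = W @ H + _EPS
            W *= (X / WH) @ H.T / np.maximum(H.sum(axis=1), _EPS)
            WH = W @ H + _EPS
            H *= W.T @ (X / WH) / np.maximum(W.sum(axis=0)[:, None], _EPS)
            obj = _kl_objective(X, W @ H + _EPS)
        else:
            WH = W @ H
            W *= (X @ H.T) / np.maximum(WH @ H.T, _EPS)
            WH = W @ H
            H *= (W.T @ X) / np.maximum(W.T @ WH, _EPS)
            obj = 0.5 * float(np.sum((X - W @ H) ** 2))
        history.append(obj)
        if prev is not None and abs(prev - obj) <= tol * max(abs(prev), _EPS):
            break
        prev = obj
    return W, H, history


def nmf_factorize(X: pd.DataFrame, k: int, n_init: int = 50,
                  max_iter: int = 500, tol: float = 1e-5,
                  seed=0, loss: str = "kl") -> SignatureModel:
    """Best-of-``n_init`` seeded multiplicative-update factorization.

    Raises if X has an all-zero row or column (an unreported AE or drug
    cannot be factorized) or if k is out of range.
    """
    check_counts(X)
    arr = X.to_numpy(dtype=float)
    p, n = arr.shape
    zero_rows = X.index[arr.sum(axis=1) == 0]
    if len(zero_rows):
        raise ValueError(f"all-zero AE row(s): {list(zero_rows[:5])}")
    zero_cols = X.columns[arr.sum(axis=0) == 0]
    if len(zero_cols):
        raise ValueError(f"all-zero drug column(s): {list(zero_cols[:5])}")
    if not (1 <= k < min(p, n)):
        raise ValueError(f"k={k} out of range [1, {min(p, n) - 1}]")
    if loss not in ("kl", "frobenius"):
        raise ValueError("loss must be 'kl' or 'frobenius'")

    seed_key = list(np.atleast_1d(seed))
    best = None
    objectives = np.empty(n_init)
    for r in range(n_init):
        rng = np.random.default_rng(seed_key + [r])
        W, H, history = _factorize_once(arr, k, rng, max_iter, tol, loss)
        objectives[r] = history[-1]
        if best is None or history[-1] < best[2][-1]:
            best = (W, H, history)

    W, H, history = best
    colsum = W.sum(axis=0)
    W = W / colsum
    H = H * colsum[:, None]
    sig_names = [f"S{v + 1}" for v in range(k)]
    return SignatureModel(
        W=pd.DataFrame(W, index=X.index, columns=sig_names),
        H=pd.DataFrame(H, index=sig_names, columns=X.columns),
        k=k, objective=float(history[-1]), n_init=n_init, seed=seed,
        loss=loss, history=np.asarray(history),
        restart_objectives=objectives)


def abundance_fractions(model: SignatureModel) -> pd.DataFrame:
    """H columns normalized to sum to 1: per-drug signature fractions."""
    colsum = model.H.sum(axis=0)
    zero = colsum.index[colsum == 0]
    if len(zero):
        raise ValueError(f"drug(s) explained by no signature: {list(zero)}")
    return model.H / colsum


def assign_clusters(fractions: pd.DataFrame) -> ClusterAssignment:
    """Drug -> argmax-signature cluster; ties go to the smallest index."""
    arr = fractions.to_numpy()
    labels = pd.Series(arr.argmax(axis=0) + 1, index=fractions.columns)
    prov = pd.Series("observed", index=fractions.columns, dtype=object)
    return ClusterAssignment(labels=labels, provenance=prov)


def _consensus_matrix(X, k, n_runs, seed, max_iter, tol, loss):
    arr_labels = []
    for r in range(n_runs):
        model = nmf_factorize(X, k, n_init=1, max_iter=max_iter, tol=tol,
                              seed=list(np.atleast_1d(seed)) + [k, r],
                              loss=loss)
        arr_labels.append(model.H.to_numpy().argmax(axis=0))
    labels = np.asarray(arr_labels)  # n_runs x n_drugs
    same = (labels[:, :, None] == labels[:, None, :]).mean(axis=0)
    np.fill_diagonal(same, 1.0)
    return same


def _cophenetic(consensus: np.ndarray) -> float:
    dist = squareform(1.0 - consensus, checks=False)
    if np.allclose(dist, dist[0] if dist.size else 0.0):
        return 1.0  # perfectly stable (or degenerate) consensus
    Z = linkage(dist, method="average")
    c, _ = cophenet(Z, dist)
    return float(np.clip(c, 0.0, 1.0))


def select_k(X: pd.DataFrame, k_range, n_runs: int = 20, seed=0,
             max_iter: int = 300, tol: float = 1e-5,
             loss: str = "kl") -> StabilityReport:
    """Stability-driven choice of the signature count.

    For each candidate k, ``n_runs`` independently seeded factorizations
    produce argmax cluster labels; the consensus matrix holds the fraction
    of runs in which each drug pair lands in the same cluster.  The
    selected k maximizes the cophenetic correlation between the consensus
    dendrogram and the ``1 - consensus`` distances (ties -> smallest k).
    """
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    k_range = sorted(set(int(k) for k in k_range))
    consensus, coph = {}, {}
    for k in k_range:
        consensus[k] = _consensus_matrix(X, k, n_runs, seed, max_iter, tol,
                                         loss)
        coph[k] = _cophenetic(consensus[k])
    best_k = k_range[0]
    for k in k_range:
        if coph[k] > coph[best_k] + 1e-12:
            best_k = k
    return StabilityReport(k_values=k_range, consensus=consensus,
                           cophenetic=coph, selected_k=best_k)
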