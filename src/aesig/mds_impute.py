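"""Second-stage networks: classical-MDS embedding and cross-network imputation.

Sources with incomplete drug coverage are patched from an anchor network
(the AE source, which covers every analyzed drug):

1. each similarity network is converted to squared dissimilarities
   ``d^2 = 2 (1 - s)`` (exact for cosine similarity of unit vectors);
2. classical multidimensional scaling embeds each network by eigen-
   decomposition of the double-centered matrix ``C = -1/2 H d^2 H``;
3. an ordinary-least-squares linear map (with intercept, since the two
   embeddings are centered over different drug sets) is fitted between
   anchor and target coordinates on the drugs shared by both networks;
4. coordinates of drugs missing from the target are predicted through the
   map and converted back to similarities ``s = 1 - d^2/2``, clipped to
   [0, 1].  Observed target entries are preserved verbatim.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .types import SimilarityNetwork

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DimRule:
    """Retain eigenpairs with eigenvalue > max(0, tau * lambda_1), capped.

    ``tau`` acts as a rank-detection threshold: exact low-rank inputs keep
    exactly their numerical rank, while noisy inputs are truncated at
    ``max_dim`` so the downstream regression stays well-posed at a few
    tens of shared drugs.
    """

    tau: float = 1e-8
    max_dim: int = 10

    def select(self, eigvals: np.ndarray, n: int) -> int:
        cutoff = max(0.0, self.tau * eigvals[0]) if eigvals.size else 0.0
        keep = int(np.sum(eigvals > cutoff))
        return min(keep, self.max_dim, n - 1)


@dataclass
class EmbeddingModel:
    """Low-dimensional drug coordinates from classical MDS.

    Column ``l`` of ``coords`` is the ``l``-th eigenvector scaled by
    ``sqrt(lambda_l)``, so each column's squared norm equals its eigenvalue
    and columns are centered.
    """

    ids: list
    coords: np.ndarray
    eigvals: np.ndarray
    source: str = "unknown"

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        self.eigvals = np.asarray(self.eigvals, dtype=float)
        if self.coords.shape != (len(self.ids), len(self.eigvals)):
            raise ValueError("coordinate matrix shape mismatch")
        if (self.eigvals < 0).any() or (np.diff(self.eigvals) > 1e-12).any():
            raise ValueError("eigenvalues must be nonnegative and descending")

    @property
    def dim(self) -> int:
        return len(self.eigvals)

    def coords_for(self, drugs) -> np.ndarray:
        index = {d: i for i, d in enumerate(self.ids)}
        return self.coords[[index[d] for d in drugs]]


@dataclass
class CrossNetworkMap:
    """OLS linear map between two embeddings, fitted on shared drugs."""

    B: np.ndarray
    intercept: np.ndarray
    shared: list
    residual_scale: float
    source: str = "unknown"
    target: str = "unknown"


def similarity_to_squared_dissimilarity(net: SimilarityNetwork) -> np.ndarray:
    """``d^2 = 2 (1 - s)``; zero diagonal, symmetric."""
    d2 = 2.0 * (1.0 - net.matrix)
    np.fill_diagonal(d2, 0.0)
    return (d2 + d2.T) / 2


def classical_mds(d2: np.ndarray, ids, dim_rule: DimRule | None = None,
                  source: str = "unknown") -> EmbeddingModel:
    """Classical (Torgerson) MDS of a squared-dissimilarity matrix.

    Eigendecomposes ``C = -1/2 H d2 H`` with the centering matrix
    ``H = I - J/n`` and keeps the leading nonnegative eigenpairs per
    ``dim_rule``.  When C is PSD and all positive eigenpairs are kept, the
    embedded pairwise squared distances reproduce ``d2`` exactly.
    """
    dim_rule = dim_rule or DimRule()
    d2 = np.asarray(d2, dtype=float)
    n = d2.shape[0]
    if d2.shape != (n, n) or n != len(ids):
        raise ValueError("d2 must be square and match the identifier list")
    if not np.allclose(d2, d2.T, atol=1e-8):
        raise ValueError("d2 must be symmetric")
    if (d2 < -1e-12).any() or np.abs(np.diag(d2)).max() > 1e-12:
        raise ValueError("d2 must be nonnegative with zero diagonal")

    C = d2 - d2.mean(axis=0, keepdims=True)
    C = C - C.mean(axis=1, keepdims=True)
    C *= -0.5
    C = (C + C.T) / 2
    eigvals, eigvecs = np.linalg.eigh(C)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    if eigvals[0] <= 0:
        raise ValueError("degenerate network: no positive eigenvalue")
    n_neg = int(np.sum(eigvals < -1e-10 * eigvals[0]))
    if n_neg:
        logger.info("classical_mds(%s): discarded %d negative eigenvalue(s)",
                    source, n_neg)
    k = dim_rule.select(eigvals, n)
    coords = eigvecs[:, :k] * np.sqrt(eigvals[:k])
    return EmbeddingModel(ids=list(ids), coords=coords,
                          eigvals=eigvals[:k], source=source)


def embed_network(net: SimilarityNetwork,
                  dim_rule: DimRule | None = None) -> EmbeddingModel:
    return classical_mds(similarity_to_squared_dissimilarity(net), net.ids,
                         dim_rule, source=net.source)


def fit_cross_map(source: EmbeddingModel,
                  target: EmbeddingModel) -> CrossNetworkMap:
    """OLS of target coordinates on source coordinates over shared drugs."""
    shared = sorted(set(source.ids) & set(target.ids))
    if len(shared) < source.dim + 2:
        raise ValueError(
            f"only {len(shared)} shared drugs; need at least "
            f"source dim + 2 = {source.dim + 2}")
    P = source.coords_for(shared)
    Q = target.coords_for(shared)
    design = np.column_stack([np.ones(len(shared)), P])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient design; use a smaller dim_rule")
    coef, _, _, _ = np.linalg.lstsq(design, Q, rcond=None)
    resid = Q - design @ coef
    scale = float(np.sqrt(np.mean(resid ** 2)))
    return CrossNetworkMap(B=coef[1:], intercept=coef[0], shared=shared,
                           residual_scale=scale,
                           source=source.source, target=target.source)


def impute_coordinates(cmap: CrossNetworkMap, zeta: np.ndarray) -> np.ndarray:
    """Predict target coordinates for a source-coordinate row."""
    zeta = np.asarray(zeta, dtype=float)
    if zeta.shape[-1] != cmap.B.shape[0]:
        raise ValueError(
            f"coordinate length {zeta.shape[-1]} != source dim {cmap.B.shape[0]}")
    return cmap.intercept + zeta @ cmap.B


def impute_network(source_net: SimilarityNetwork,
                   target_net: SimilarityNetwork,
                   dim_rule: DimRule | None = None) -> SimilarityNetwork:
    """Second-stage network over the union drug set.

    Observed target entries are preserved bitwise; entries involving at
    least one imputed drug are computed as ``clip(1 - d^2/2, 0, 1)`` from
    the (embedded or map-predicted) target coordinates.
    """
    dim_rule = dim_rule or DimRule()
    union = sorted(set(source_net.ids) | set(target_net.ids))
    missing_from_source = set(union) - set(source_net.ids)
    if missing_from_source:
        raise ValueError(
            "anchor network must cover every drug; missing "
            f"{sorted(missing_from_source)}")

    target_set = set(target_net.ids)
    to_impute = [d for d in union if d not in target_set]
    if not to_impute:
        out = target_net.reindex(union)
        out.stage = "second"
        return out

    src_emb = embed_network(source_net, dim_rule)
    tgt_emb = embed_network(target_net, dim_rule)
    cmap = fit_cross_map(src_emb, tgt_emb)

    coords = np.empty((len(union), tgt_emb.dim))
    observed_mask = np.array([d in target_set for d in union])
    coords[observed_mask] = tgt_emb.coords_for(
        [d for d in union if d in target_set])
    coords[~observed_mask] = impute_coordinates(
        cmap, src_emb.coords_for(to_impute))

    d2 = squareform(pdist(coords, metric="sqeuclidean"))
    S = np.clip(1.0 - d2 / 2.0, 0.0, 1.0)

    # preserve observed target entries verbatim
    obs_pos = np.flatnonzero(observed_mask)
    tgt_idx = [target_net.index_of(union[i]) for i in obs_pos]
    S[np.ix_(obs_pos, obs_pos)] = target_net.matrix[np.ix_(tgt_idx, tgt_idx)]
    S = (S + S.T) / 2
    np.fill_diagonal(S, 1.0)
    return SimilarityNetwork(ids=union, matrix=S,
                             source=target_net.source, stage="second")
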