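"""Similarity network fusion of the second-stage networks.

Cross-diffusion in the style of multi-omic patient-network fusion: each
network is split into a full row-stochastic kernel P and a sparse K-nearest
neighbor kernel S, then each P is iteratively diffused through the average
of the other networks' P via its own local kernel,
``P_v <- S_v . mean_{w != v}(P_w) . S_v^T``.  Inputs are consumed as
similarities directly (they already live in [0, 1]); no Gaussian
re-kernelization is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .types import SimilarityNetwork


@dataclass(frozen=True)
class FusionParams:
    """K: neighborhood size; t: diffusion iterations; mu: kernel bandwidth
    scale (kept for interface compatibility, unused by the direct-similarity
    kernels)."""

    K: int = 0  # 0 -> max(3, n // 10)
    t: int = 20
    mu: float = 0.5

    def resolve_K(self, n: int) -> int:
        K = self.K if self.K >= 1 else max(3, n // 10)
        if K >= n:
            raise ValueError(f"K={K} must be smaller than n={n}")
        return K

    def __post_init__(self):
        if self.t < 1:
            raise ValueError("t must be >= 1")


def full_kernel(net: SimilarityNetwork) -> np.ndarray:
    """Row-normalized full kernel: off-diagonal mass 1/2, diagonal 1/2."""
    S = net.matrix.copy()
    np.fill_diagonal(S, 0.0)
    rowsum = S.sum(axis=1)
    if (rowsum <= 0).any():
        bad = [net.ids[i] for i in np.flatnonzero(rowsum <= 0)]
        raise ValueError(f"row(s) with zero off-diagonal similarity: {bad}")
    P = S / (2.0 * rowsum[:, None])
    np.fill_diagonal(P, 0.5)
    return P


def knn_kernel(net: SimilarityNetwork, K: int) -> np.ndarray:
    """Sparse local kernel over each drug's K most-similar neighbors.

    Ties at the K-th neighbor are broken by drug-identifier lexicographic
    order, so the kernel is deterministic.
    """
    n = net.n
    if K >= n:
        raise ValueError("K must be smaller than the number of drugs")
    S = net.matrix
    out = np.zeros_like(S)
    for i in range(n):
        order = sorted((j for j in range(n) if j != i),
                       key=lambda j: (-S[i, j], net.ids[j]))
        nbrs = order[:K]
        mass = S[i, nbrs].sum()
        if mass <= 0:
            raise ValueError(
                f"drug {net.ids[i]!r} has zero similarity to its neighbors")
        out[i, nbrs] = S[i, nbrs] / mass
    return out


def snf_fuse(nets: list, params: FusionParams | None = None) -> SimilarityNetwork:
    """Fuse >= 2 networks over an identical drug set into one network."""
    params = params or FusionParams()
    if not nets:
        raise ValueError("no networks to fuse")
    ids = sorted(nets[0].ids)
    nets = [net.reindex(ids) for net in nets]
    for net in nets:
        if sorted(net.ids) != ids:
            raise ValueError("all networks must share an identical drug set")

    if len(nets) == 1:
        warnings.warn("single network supplied; returning its normalized "
                      "kernel without fusion")
        P = full_kernel(nets[0])
        M = (P + P.T) / 2
        M = M / M.max()
        np.fill_diagonal(M, 1.0)
        return SimilarityNetwork(ids=ids, matrix=np.clip(M, 0, 1),
                                 source="fused", stage="fused")

    n = len(ids)
    K = params.resolve_K(n)
    P = [full_kernel(net) for net in nets]
    S = [knn_kernel(net, K) for net in nets]
    m = len(nets)
    for _ in range(params.t):
        new = []
        for v in range(m):
            others = sum(P[w] for w in range(m) if w != v) / (m - 1)
            Pv = S[v] @ others @ S[v].T
            new.append((Pv + Pv.T) / 2)
        P = new
    M = sum(P) / m
    M = (M + M.T) / 2
    M = np.clip(M, 0.0, None)
    # the diffused matrix carries stationary-mass (degree) bias: drugs with
    # large total affinity dominate every row; symmetric degree
    # normalization turns it back into a comparable affinity
    np.fill_diagonal(M, 0.0)
    mass = M.sum(axis=1)
    if (mass <= 0).any():
        raise ValueError("fusion produced an isolated drug")
    M = M / np.sqrt(np.outer(mass, mass))
    off_max = M.max()
    if off_max > 0:
        M = M / off_max
    np.fill_diagonal(M, 1.0)
    return SimilarityNetwork(ids=ids, matrix=np.clip(M, 0.0, 1.0),
                             source="fused", stage="fused")
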