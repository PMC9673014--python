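"""Drug-tissue association by interactome network proximity.

Tissue-specific genes are scored by the cross-tissue z-score

    Z_tg = (Ebar_tg - Ebar_g) / S_g

(mean and sd taken over per-tissue means), and the top-scoring genes per
tissue form the tissue module B_t.  A drug's target module A_j is compared
to B_t by the size-normalized closest-pair shortest-path distance

    d_jt = ( sum_{a in A} min_b d(a,b) + sum_{b in B} min_a d(a,b) )
           / (|A| + |B|)

on the unweighted gene-gene network.  Significance is the fraction of
size-matched uniform random gene-set draws whose distance falls strictly
below the observed distance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class ProximityResult:
    drug: str
    tissue: str
    distance: float
    null_distances: np.ndarray
    significance: float


class GeneNetworkDistances:
    """All-pairs BFS distance cache for one gene network.

    Unreachable pairs are assigned ``diameter(largest component) + 1`` so
    that disconnection is penalized while keeping the module-size
    denominator truthful.
    """

    def __init__(self, graph: nx.Graph):
        if any(graph.has_edge(u, u) for u in graph):
            raise ValueError("gene network must have no self-loops")
        self.graph = graph
        self.nodes = sorted(graph.nodes)
        self.index = {g: i for i, g in enumerate(self.nodes)}
        n = len(self.nodes)
        dist = np.full((n, n), -1, dtype=np.int32)
        for src, lengths in nx.all_pairs_shortest_path_length(graph):
            i = self.index[src]
            for dst, d in lengths.items():
                dist[i, self.index[dst]] = d
        dmax = int(dist.max())
        unreachable = dist < 0
        if unreachable.any():
            logger.info("gene network is disconnected; unreachable pairs "
                        "penalized at diameter + 1 = %d", dmax + 1)
        dist[unreachable] = dmax + 1
        self.dist = dist

    def subset(self, genes, label: str):
        present = sorted(set(genes) & set(self.index))
        dropped = len(set(genes)) - len(present)
        if dropped:
            logger.info("%s: dropped %d gene(s) absent from the network",
                        label, dropped)
        if not present:
            raise ValueError(f"module {label!r} empty after network filtering")
        return np.array([self.index[g] for g in present])


def tissue_zscores(expr: pd.DataFrame) -> pd.DataFrame:
    """Cross-tissue z-score matrix from a gene x tissue mean-expression table.

    Genes with zero cross-tissue standard deviation score 0 in every
    tissue.
    """
    if expr.shape[1] < 2:
        raise ValueError("need at least two tissues")
    arr = expr.to_numpy(dtype=float)
    mean = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, ddof=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (arr - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    return pd.DataFrame(z, index=expr.index, columns=expr.columns)


def top_tissue_genes(Z: pd.DataFrame, n_top: int = 200) -> dict:
    """Top ``n_top`` genes per tissue by descending z-score.

    Boundary ties are broken by gene-identifier lexicographic order.
    """
    if n_top > Z.shape[0]:
        raise ValueError("n_top exceeds the number of genes")
    out = {}
    for tissue in Z.columns:
        ranked = sorted(Z.index, key=lambda g: (-Z.at[g, tissue], g))
        out[tissue] = set(ranked[:n_top])
    return out


def module_distance(A, B, net: GeneNetworkDistances,
                    label_a: str = "A", label_b: str = "B") -> float:
    """Size-normalized closest-pair distance between two gene modules."""
    ia = net.subset(A, label_a)
    ib = net.subset(B, label_b)
    block = net.dist[np.ix_(ia, ib)]
    return float((block.min(axis=1).sum() + block.min(axis=0).sum())
                 / (len(ia) + len(ib)))


def proximity_significance(targets, tissue_genes, net: GeneNetworkDistances,
                           n_perm: int = 100, seed=0,
                           drug: str = "drug",
                           tissue: str = "tissue") -> ProximityResult:
    """Permutation significance of one drug-tissue module distance.

    Each permutation draws, uniformly without replacement from all network
    genes, a random set matching |A| and a random set matching |B|;
    significance is the fraction of null distances strictly below the
    observed one (so a 0 is possible and reported as such).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    ia = net.subset(targets, f"targets[{drug}]")
    ib = net.subset(tissue_genes, f"tissue[{tissue}]")
    n = len(net.nodes)
    if len(ia) > n or len(ib) > n:
        raise ValueError("module larger than the network")
    observed = module_distance(targets, tissue_genes, net)
    rng = np.random.default_rng(np.atleast_1d(seed))
    null = np.empty(n_perm)
    for r in range(n_perm):
        ra = rng.choice(n, size=len(ia), replace=False)
        rb = rng.choice(n, size=len(ib), replace=False)
        block = net.dist[np.ix_(ra, rb)]
        null[r] = (block.min(axis=1).sum() + block.min(axis=0).sum()) \
            / (len(ra) + len(rb))
    sig = float(np.mean(null < observed))
    return ProximityResult(drug=drug, tissue=tissue, distance=observed,
                           null_distances=null, significance=sig)


def proximity_heatmap_table(drug_targets: dict, tissues: dict,
                            net: GeneNetworkDistances, n_perm: int = 100,
                            seed=0) -> pd.DataFrame:
    """Long-format (drug, tissue, distance, significance) table.

    A significance of exactly 0 is mapped to the sentinel
    ``log10(n_perm) + 1`` on the -log10 scale.
    """
    sentinel = np.log10(n_perm) + 1
    rows = []
    seed_key = list(np.atleast_1d(seed))
    for di, drug in enumerate(sorted(drug_targets)):
        for ti, tissue in enumerate(sorted(tissues)):
            res = proximity_significance(
                drug_targets[drug], tissues[tissue], net, n_perm=n_perm,
                seed=seed_key + [di, ti], drug=drug, tissue=tissue)
            neglog = sentinel if res.significance == 0 \
                else -np.log10(res.significance)
            rows.append({"drug": drug, "tissue": tissue,
                         "distance": res.distance,
                         "significance": res.significance,
                         "neg_log10_significance": neglog})
    return pd.DataFrame(rows)
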