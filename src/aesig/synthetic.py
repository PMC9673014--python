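"""Synthetic inputs with the statistical structure the pipeline assumes.

In production this pipeline consumes proprietary or licensed resources (a
spontaneous adverse-event reporting extract, bioassay and chemical
fingerprints, a perturbational expression library, a tissue expression
atlas, a drug-target database, and a licensed AE ontology).  This module
generates stand-ins for every one of them, together with the ground truth
needed for recovery tests:

* report counts drawn Poisson from a planted low-rank nonnegative product
  ``W_true @ H_true``, with disjoint high-probability AE blocks per signature
  so the signatures are identifiable;
* multi-source drug-drug similarity networks derived from shared latent
  drug coordinates, with per-source orthogonal distortions, coordinate
  noise, and per-source drug coverage gaps (the AE-like source always has
  full coverage and anchors the imputation);
* log-fold-change expression profiles with cluster-pair-specific planted
  discriminant genes;
* a gene-gene network, tissue expression means with planted tissue-specific
  gene blocks, and drug target sets concentrated near a tissue's block for
  designated tissue-associated drugs;
* an AE -> SOC category map whose planted category per signature coincides
  with that signature's high-probability AE block.

Every generator is deterministic in the configuration seed.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .types import ClusterAssignment, SimilarityNetwork
from . import io as aio

SOURCE_NAMES = ("ae", "bioassay", "chemical", "expression")

# Latent drug coordinates live in the positive cone around LATENT_SHIFT * 1 so
# that cosine similarities of mapped coordinates stay in [0, 1]; see docs.
LATENT_SHIFT = 3.0
CLUSTER_CENTER_NORM = 4.0
CLUSTER_WITHIN_SD = 0.3


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic study.

    Defaults describe a desk-scale cohort: 60 drugs (half with rich AE
    feedback, half essentially unreported, mirroring the approved-versus-
    trial-stage split), 120 AE terms, four planted signatures, and four
    data sources of which only the AE source covers every drug.
    """

    seed: int = 0
    n_drugs: int = 60
    n_aes: int = 120
    k_true: int = 4
    count_scale: float = 600.0
    latent_dim: int = 3
    n_sources: int = 4
    coverage: tuple = (1.0, 0.8, 0.8, 0.8)
    map_noise_sd: float = 0.05
    n_genes: int = 300
    n_discriminant: int = 10
    effect_size: float = 3.0
    n_tissues: int = 5
    n_soc: int = 8
    label_fraction: float = 0.5
    low_count_scale: float = 8.0

    def __post_init__(self):
        for name in ("n_drugs", "n_aes", "k_true", "latent_dim", "n_sources",
                     "n_genes", "n_discriminant", "n_tissues", "n_soc"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if self.count_scale <= 0 or self.low_count_scale <= 0:
            raise ValueError("count scales must be positive")
        if self.map_noise_sd < 0:
            raise ValueError("map_noise_sd must be nonnegative")
        cov = self.coverage if isinstance(self.coverage, (tuple, list)) \
            else (self.coverage,) * self.n_sources
        if len(cov) != self.n_sources:
            raise ValueError("coverage must have one fraction per source")
        if any(not (0 < c <= 1) for c in cov):
            raise ValueError("coverage fractions must lie in (0, 1]")
        object.__setattr__(self, "coverage", tuple(cov))
        if not (0 < self.label_fraction <= 1):
            raise ValueError("label_fraction must lie in (0, 1]")

    def drug_ids(self):
        width = len(str(self.n_drugs))
        return [f"DRUG_{i:0{width}d}" for i in range(1, self.n_drugs + 1)]

    def ae_ids(self):
        width = len(str(self.n_aes))
        return [f"AE_{i:0{width}d}" for i in range(1, self.n_aes + 1)]

    def gene_ids(self):
        width = len(str(self.n_genes))
        return [f"G{i:0{width}d}" for i in range(1, self.n_genes + 1)]

    def tissue_ids(self):
        return [f"TISSUE_{i}" for i in range(1, self.n_tissues + 1)]

    def soc_ids(self):
        return [f"SOC_{i:02d}" for i in range(1, self.n_soc + 1)]


@dataclass
class GroundTruth:
    """Planted generative quantities, populated per generator."""

    true_W: pd.DataFrame | None = None
    true_H: pd.DataFrame | None = None
    true_clusters: pd.Series | None = None
    signature_blocks: dict = field(default_factory=dict)
    labeled_drugs: list = field(default_factory=list)
    latent_coords: pd.DataFrame | None = None
    source_maps: dict = field(default_factory=dict)
    observed_drugs: dict = field(default_factory=dict)
    true_similarities: dict = field(default_factory=dict)
    planted_genes: dict = field(default_factory=dict)
    tissue_blocks: dict = field(default_factory=dict)
    tissue_drugs: dict = field(default_factory=dict)
    enriched_soc: dict = field(default_factory=dict)


def _rng(cfg: SyntheticConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, stream])


# ---------------------------------------------------------------------------
# AE report counts
# ---------------------------------------------------------------------------

def gen_ae_counts(cfg: SyntheticConfig, count_scale=None):
    """Poisson report counts from a planted column-stochastic W and H.

    Each signature owns a disjoint block of high-probability AEs (85% of
    its probability mass), with the remaining 15% spread over AEs that
    belong to no block; pairwise cosines between planted signatures stay
    well below 0.3.  ``count_scale`` may be a scalar or a per-drug vector
    of mean total report counts (the fixture uses the latter to emulate
    drugs with scarce feedback).
    """
    if cfg.k_true < 1:
        raise ValueError("k_true must be >= 1")
    if cfg.n_aes <= cfg.k_true or cfg.k_true >= min(cfg.n_aes, cfg.n_drugs):
        raise ValueError("k_true must be smaller than both n_aes and n_drugs")
    rng = _rng(cfg, 0)
    aes, drugs = cfg.ae_ids(), cfg.drug_ids()
    k = cfg.k_true

    block_size = max(3, cfg.n_aes // (2 * k))
    blocks = {v: list(range(v * block_size, (v + 1) * block_size))
              for v in range(k)}
    background = list(range(k * block_size, cfg.n_aes))
    if not background:
        raise ValueError("n_aes too small to leave background AEs")

    W = np.zeros((cfg.n_aes, k))
    for v in range(k):
        W[blocks[v], v] = 0.85 * rng.dirichlet(np.full(block_size, 5.0))
        W[background, v] = 0.15 * rng.dirichlet(np.full(len(background), 2.0))

    clusters = np.array([j % k for j in range(cfg.n_drugs)])
    H = 0.25 * rng.dirichlet(np.ones(k), size=cfg.n_drugs).T
    H[clusters, np.arange(cfg.n_drugs)] += 0.75

    scale = np.asarray(cfg.count_scale if count_scale is None else count_scale,
                       dtype=float)
    lam = (W @ H) * scale
    X = rng.poisson(lam)

    sig_names = [f"S{v + 1}" for v in range(k)]
    truth = GroundTruth(
        true_W=pd.DataFrame(W, index=aes, columns=sig_names),
        true_H=pd.DataFrame(H, index=sig_names, columns=drugs),
        true_clusters=pd.Series(clusters + 1, index=drugs),
        signature_blocks={v + 1: [aes[i] for i in blocks[v]] for v in range(k)},
    )
    counts = pd.DataFrame(X, index=aes, columns=drugs)
    return counts, truth


# ---------------------------------------------------------------------------
# Multi-source similarity networks
# ---------------------------------------------------------------------------

def _latent_coordinates(cfg, rng, clusters=None) -> np.ndarray:
    d = cfg.latent_dim
    if clusters is None:
        return LATENT_SHIFT + rng.standard_normal((cfg.n_drugs, d))
    labels = np.asarray(clusters)
    uniq = np.unique(labels)
    # well-separated positive-orthant center directions: coordinate axes,
    # then normalized pair diagonals; deterministic in the dimension
    dirs = [np.eye(d)[i] for i in range(d)]
    for i in range(d):
        for j in range(i + 1, d):
            v = np.eye(d)[i] + np.eye(d)[j]
            dirs.append(v / np.linalg.norm(v))
    dirs.append(np.ones(d) / np.sqrt(d))
    if len(uniq) > len(dirs):
        raise ValueError("latent_dim too small for this many clusters")
    centers = CLUSTER_CENTER_NORM * np.asarray(dirs[:len(uniq)])
    Z = np.empty((len(labels), d))
    for ci, c in enumerate(uniq):
        mask = labels == c
        Z[mask] = centers[ci] + CLUSTER_WITHIN_SD * rng.standard_normal(
            (mask.sum(), d))
    return Z


def _cosine_similarity_matrix(coords: np.ndarray) -> np.ndarray:
    U = coords / np.linalg.norm(coords, axis=1, keepdims=True)
    S = np.clip(U @ U.T, 0.0, 1.0)
    np.fill_diagonal(S, 1.0)
    return (S + S.T) / 2


def gen_multisource_networks(cfg: SyntheticConfig, clusters=None,
                             identity_maps: bool = False):
    """First-stage similarity networks from shared latent drug coordinates.

    Drug coordinates are drawn around a positive-cone center (cluster-
    structured when ``clusters`` is supplied); each source applies its own
    random orthogonal distortion plus Gaussian coordinate noise, and
    similarity is ``1 - d^2/2`` of the unit-normalized mapped coordinates,
    i.e. their cosine, clipped to [0, 1].  Source 1 (the AE-like source)
    observes every drug; every other source observes a seeded random subset
    of fraction ``coverage[s]``.
    """
    if cfg.n_sources < 2:
        raise ValueError("need at least two sources")
    rng = _rng(cfg, 1)
    drugs = np.array(cfg.drug_ids())
    n, d = cfg.n_drugs, cfg.latent_dim
    Z = _latent_coordinates(cfg, rng, clusters)

    names = list(SOURCE_NAMES[:cfg.n_sources]) + [
        f"source{s}" for s in range(len(SOURCE_NAMES), cfg.n_sources)]
    nets, truth_maps, observed, true_sims = [], {}, {}, {}
    for s, name in enumerate(names):
        if identity_maps:
            R = np.eye(d)
        else:
            R, _ = np.linalg.qr(rng.standard_normal((d, d)))
        mapped = Z @ R.T + cfg.map_noise_sd * rng.standard_normal((n, d))
        S_full = _cosine_similarity_matrix(mapped)
        true_sims[name] = pd.DataFrame(S_full, index=drugs, columns=drugs)
        truth_maps[name] = R

        if s == 0 or cfg.coverage[s] >= 1.0:
            keep = np.arange(n)
        else:
            n_keep = int(round(cfg.coverage[s] * n))
            keep = np.sort(rng.choice(n, size=n_keep, replace=False))
        if s > 0 and len(keep) < d + 2:
            raise ValueError(
                f"source {name!r} shares only {len(keep)} drugs with the "
                f"anchor; need at least latent_dim + 2 = {d + 2}")
        observed[name] = [str(x) for x in drugs[keep]]
        nets.append(SimilarityNetwork(
            ids=observed[name], matrix=S_full[np.ix_(keep, keep)],
            source=name, stage="first"))

    truth = GroundTruth(
        latent_coords=pd.DataFrame(Z, index=drugs,
                                   columns=[f"dim{i+1}" for i in range(d)]),
        source_maps=truth_maps, observed_drugs=observed,
        true_similarities=true_sims)
    return nets, truth


# ---------------------------------------------------------------------------
# Expression profiles with planted discriminant genes
# ---------------------------------------------------------------------------

def gen_expression_profiles(cfg: SyntheticConfig, clusters: ClusterAssignment):
    """Gene x drug log-fold-change matrix with planted cluster-pair signals.

    Background is N(0, 1); for each unordered cluster pair a disjoint set of
    ``n_discriminant`` genes is shifted by +effect_size/2 in the first
    cluster of the pair and -effect_size/2 in the second, so the planted
    between-cluster mean gap equals ``effect_size``.
    """
    labels = clusters.labels if isinstance(clusters, ClusterAssignment) \
        else pd.Series(clusters, dtype=int)
    uniq = sorted(labels.unique())
    if len(uniq) < 2:
        raise ValueError("need at least two clusters")
    sizes = labels.value_counts()
    if (sizes < 2).any():
        raise ValueError("every cluster needs at least two drugs")
    pairs = list(itertools.combinations(uniq, 2))
    if cfg.n_discriminant * len(pairs) > cfg.n_genes:
        raise ValueError("not enough genes for disjoint planted sets")

    rng = _rng(cfg, 2)
    genes = cfg.gene_ids()
    drugs = list(labels.index)
    E = rng.standard_normal((cfg.n_genes, len(drugs)))
    planted = {}
    cursor = 0
    half = cfg.effect_size / 2
    for (a, b) in pairs:
        gidx = np.arange(cursor, cursor + cfg.n_discriminant)
        cursor += cfg.n_discriminant
        E[np.ix_(gidx, np.flatnonzero(labels.values == a))] += half
        E[np.ix_(gidx, np.flatnonzero(labels.values == b))] -= half
        planted[(a, b)] = [genes[i] for i in gidx]

    profile = pd.DataFrame(E, index=genes, columns=drugs)
    return profile, GroundTruth(planted_genes=planted)


# ---------------------------------------------------------------------------
# Gene network, tissue expression, drug targets
# ---------------------------------------------------------------------------

def gen_tissue_and_targets(cfg: SyntheticConfig, n_targets: int = 5,
                           block_size: int = 20, mean_degree: float = 6.0):
    """Gene network, tissue expression means, and drug target sets.

    The gene-gene network is the giant component of a seeded Erdos-Renyi
    graph with the given mean degree.  Each tissue owns a disjoint planted
    block of genes whose per-tissue mean is elevated by 3 expression units.
    The first half of the drug roster is tissue-associated: drug ``j``
    targets genes within one hop of tissue ``j mod n_tissues``'s block.
    The second half are null drugs with uniformly sampled targets.
    """
    if cfg.n_genes < 50:
        raise ValueError("need at least 50 genes")
    rng = _rng(cfg, 3)
    genes = cfg.gene_ids()
    p_edge = mean_degree / cfg.n_genes
    g_full = nx.fast_gnp_random_graph(cfg.n_genes, p_edge,
                                      seed=int(rng.integers(2**31)))
    giant = max(nx.connected_components(g_full), key=len)
    graph = nx.relabel_nodes(g_full.subgraph(giant).copy(),
                             {i: genes[i] for i in giant})
    nodes = sorted(graph.nodes)
    if cfg.n_tissues * block_size > len(nodes):
        raise ValueError("tissue blocks exceed network size")

    perm = rng.permutation(len(nodes))
    tissue_blocks = {}
    for t, tissue in enumerate(cfg.tissue_ids()):
        idx = perm[t * block_size:(t + 1) * block_size]
        tissue_blocks[tissue] = sorted(nodes[i] for i in idx)

    base = rng.normal(5.0, 1.0, size=len(nodes))
    expr = base[:, None] + rng.normal(0.0, 0.2,
                                      size=(len(nodes), cfg.n_tissues))
    expr = pd.DataFrame(expr, index=nodes, columns=cfg.tissue_ids())
    for tissue, block in tissue_blocks.items():
        expr.loc[block, tissue] += 3.0

    drugs = cfg.drug_ids()
    n_assoc = cfg.n_drugs // 2
    targets, tissue_drugs = {}, {}
    tissues = cfg.tissue_ids()
    for j, drug in enumerate(drugs):
        if j < n_assoc:
            tissue = tissues[j % cfg.n_tissues]
            block = tissue_blocks[tissue]
            hood = sorted({nb for b in block
                           for nb in graph.neighbors(b)} - set(block))
            tissue_drugs[drug] = tissue
            # targets of a tissue-associated drug are mostly the tissue's
            # own specific genes, with a minority of first neighbors
            n_block = max(1, int(round(0.8 * n_targets)))
            pick = list(rng.choice(len(block), size=min(n_block, len(block)),
                                   replace=False))
            chosen = {block[i] for i in pick}
            n_rest = n_targets - len(chosen)
            if n_rest > 0 and hood:
                extra = rng.choice(len(hood), size=min(n_rest, len(hood)),
                                   replace=False)
                chosen |= {hood[i] for i in extra}
            targets[drug] = chosen
        else:
            pick = rng.choice(len(nodes), size=min(n_targets, len(nodes)),
                              replace=False)
            targets[drug] = {nodes[i] for i in pick}

    truth = GroundTruth(tissue_blocks=tissue_blocks, tissue_drugs=tissue_drugs)
    return graph, expr, targets, truth


# ---------------------------------------------------------------------------
# SOC mapping
# ---------------------------------------------------------------------------

def gen_soc_mapping(cfg: SyntheticConfig, truth: GroundTruth) -> dict:
    """AE -> SOC map with one planted enriched category per signature.

    Signature ``v``'s high-probability AE block is assigned wholly to the
    ``v``-th SOC category; all remaining AEs are assigned uniformly at
    random over every category.
    """
    if cfg.n_soc < cfg.k_true:
        raise ValueError("need at least one SOC category per signature")
    if not truth.signature_blocks:
        raise ValueError("ground truth lacks signature blocks; "
                         "run gen_ae_counts first")
    rng = _rng(cfg, 4)
    socs = cfg.soc_ids()
    mapping = {}
    for v, block in truth.signature_blocks.items():
        for ae in block:
            mapping[ae] = socs[v - 1]
        truth.enriched_soc[v] = socs[v - 1]
    rest = [ae for ae in cfg.ae_ids() if ae not in mapping]
    draws = rng.integers(0, cfg.n_soc, size=len(rest))
    for ae, t in zip(rest, draws):
        mapping[ae] = socs[t]
    return mapping


# ---------------------------------------------------------------------------
# Complete fixture
# ---------------------------------------------------------------------------

def generate_fixture(cfg: SyntheticConfig, outdir) -> GroundTruth:
    """Write a complete pipeline input directory plus ground-truth JSON.

    Drugs in the first ``label_fraction`` of each cluster receive rich AE
    feedback (mean total ``count_scale`` reports); the rest receive
    ``low_count_scale`` reports, below any sensible feedback threshold, so
    the pipeline must label them by network propagation.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # counts: per-drug scale splits the roster into AE-rich / AE-poor drugs
    _, truth = gen_ae_counts(cfg)  # probe run, only for the cluster layout
    labels = truth.true_clusters
    labeled = []
    for c in sorted(labels.unique()):
        members = list(labels.index[labels == c])
        n_rich = max(2, int(round(cfg.label_fraction * len(members))))
        labeled.extend(members[:n_rich])
    scale = np.where(pd.Index(labels.index).isin(labeled),
                     cfg.count_scale, cfg.low_count_scale)
    counts, truth = gen_ae_counts(cfg, count_scale=scale)
    truth.labeled_drugs = sorted(labeled)
    aio.write_counts(counts, outdir / "counts.tsv")

    nets, net_truth = gen_multisource_networks(cfg, clusters=truth.true_clusters)
    truth.latent_coords = net_truth.latent_coords
    truth.source_maps = net_truth.source_maps
    truth.observed_drugs = net_truth.observed_drugs
    truth.true_similarities = net_truth.true_similarities
    for net in nets[1:]:
        aio.write_similarity(net, outdir / f"similarity_{net.source}.tsv")

    profile, expr_truth = gen_expression_profiles(cfg, truth.true_clusters)
    truth.planted_genes = expr_truth.planted_genes
    aio.write_matrix(profile, outdir / "expression.tsv")

    graph, tissue_expr, targets, tt_truth = gen_tissue_and_targets(cfg)
    truth.tissue_blocks = tt_truth.tissue_blocks
    truth.tissue_drugs = tt_truth.tissue_drugs
    aio.write_edge_list(graph, outdir / "gene_network.tsv")
    aio.write_matrix(tissue_expr, outdir / "tissue_expression.tsv")
    aio.write_drug_targets(targets, outdir / "drug_targets.tsv")

    mapping = gen_soc_mapping(cfg, truth)
    aio.write_soc_mapping(mapping, outdir / "soc_mapping.tsv")

    aio.write_json({
        "config": asdict(cfg),
        "true_clusters": truth.true_clusters.to_dict(),
        "labeled_drugs": truth.labeled_drugs,
        "signature_blocks": truth.signature_blocks,
        "enriched_soc": truth.enriched_soc,
        "planted_genes": {f"{a}-{b}": v
                          for (a, b), v in truth.planted_genes.items()},
        "tissue_drugs": truth.tissue_drugs,
        "tissue_blocks": truth.tissue_blocks,
    }, outdir / "ground_truth.json")
    return truth
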