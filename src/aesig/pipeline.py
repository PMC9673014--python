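"""End-to-end orchestration and safety-cluster label propagation.

The pipeline runs ten stages in order: first-stage similarity networks,
MDS imputation of incompletely covered sources against the AE anchor, SNF
fusion, NMF of the AE-rich drugs' count matrix (with stability-driven rank
selection when requested), abundance fractions, observed cluster labels,
propagation of labels to the remaining drugs over the fused network, SOC
enrichment, drug-tissue network proximity, and sparse-LDA discriminant
genes.  Every intermediate is written as plain TSV/JSON and a manifest
records inputs' checksums, the seed, and all parameters.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as aio
from .types import ClusterAssignment, SimilarityNetwork
from .similarity import ae_profile_similarity
from .mds_impute import DimRule, impute_network
from .fusion import FusionParams, snf_fuse
from .nmf import (abundance_fractions, assign_clusters, nmf_factorize,
                  select_k)
from .enrichment import enrichment_table
from .proximity import (GeneNetworkDistances, proximity_heatmap_table,
                        tissue_zscores, top_tissue_genes)
from .slda import heatmap_table, pairwise_discriminant_sets

logger = logging.getLogger(__name__)

STAGES = (
    "first_stage_networks",
    "imputation",
    "fusion",
    "nmf",
    "abundance_fractions",
    "observed_clusters",
    "label_propagation",
    "soc_enrichment",
    "tissue_proximity",
    "slda_discriminant",
)


class PipelineError(RuntimeError):
    def __init__(self, stage, cause):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Paths and parameters for a full run.

    ``k`` may be an integer signature count or ``"auto"`` for
    stability-driven selection over ``k_range``.  ``min_reports`` is the
    AE-feedback threshold above which a drug's counts enter the NMF.
    """

    counts: str
    similarities: list
    soc_mapping: str
    expression: str
    gene_network: str
    tissue_expression: str
    drug_targets: str
    outdir: str = "aesig_out"
    k: object = "auto"
    k_range: tuple = (2, 3, 4, 5, 6)
    n_init: int = 50
    min_reports: int = 20
    n_perm: int = 100
    n_top: int = 200
    K_label: int = 5
    fusion: FusionParams = field(default_factory=FusionParams)
    dim_rule: DimRule = field(default_factory=DimRule)
    merge_control: bool = True
    seed: int = 0

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        raw = aio.read_json(path)
        if "fusion" in raw:
            raw["fusion"] = FusionParams(**raw["fusion"])
        if "dim_rule" in raw:
            raw["dim_rule"] = DimRule(**raw["dim_rule"])
        if "k_range" in raw:
            raw["k_range"] = tuple(raw["k_range"])
        return cls(**raw)


def nearest_neighbors(fused: SimilarityNetwork, drug: str, K: int) -> list:
    """The K drugs most similar to ``drug`` (query excluded), ties by id."""
    if K >= fused.n:
        raise ValueError("K must be smaller than the network size")
    try:
        i = fused.index_of(drug)
    except KeyError:
        import difflib
        near = difflib.get_close_matches(drug, fused.ids, n=3)
        raise KeyError(f"drug {drug!r} not in network; did you mean {near}?")
    order = sorted((j for j in range(fused.n) if j != i),
                   key=lambda j: (-fused.matrix[i, j], fused.ids[j]))
    return [fused.ids[j] for j in order[:K]]


def propagate_labels(fused: SimilarityNetwork, observed: ClusterAssignment,
                     K_label: int = 5) -> ClusterAssignment:
    """Similarity-weighted K-NN vote from observed-labeled drugs.

    Each unlabeled drug polls its ``K_label`` most-similar observed-labeled
    drugs; the cluster with the largest total similarity wins, ties going
    to the smallest cluster index.  Observed labels are never altered.
    """
    obs = observed.labels[observed.provenance == "observed"]
    obs = obs[[d for d in obs.index if d in fused.ids]]
    if obs.empty:
        raise ValueError("no observed labels to propagate from")
    labels, prov, votes = {}, {}, {}
    for d in obs.index:
        labels[d] = int(obs[d])
        prov[d] = "observed"
    labeled_idx = [(fused.index_of(d), d) for d in obs.index]
    for d in fused.ids:
        if d in labels:
            continue
        i = fused.index_of(d)
        ranked = sorted(labeled_idx,
                        key=lambda t: (-fused.matrix[i, t[0]], t[1]))
        support = ranked[:K_label]
        weight = {}
        for j, nb in support:
            c = int(obs[nb])
            weight[c] = weight.get(c, 0.0) + float(fused.matrix[i, j])
        winner = min(weight, key=lambda c: (-weight[c], c))
        labels[d] = winner
        prov[d] = "propagated"
        votes[d] = [{"neighbor": nb, "weight": float(fused.matrix[i, j]),
                     "cluster": int(obs[nb])} for j, nb in support]
    idx = list(fused.ids)
    return ClusterAssignment(labels=pd.Series(labels)[idx],
                             provenance=pd.Series(prov)[idx], votes=votes)


def _sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run all ten stages; returns the manifest dictionary.

    On a stage failure, partial outputs are retained alongside a FAILED
    marker naming the stage.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "seed": cfg.seed,
        "parameters": {
            "k": cfg.k, "k_range": list(cfg.k_range), "n_init": cfg.n_init,
            "min_reports": cfg.min_reports, "n_perm": cfg.n_perm,
            "n_top": cfg.n_top, "K_label": cfg.K_label,
            "fusion": asdict(cfg.fusion), "dim_rule": asdict(cfg.dim_rule),
            "merge_control": cfg.merge_control,
            "label_rule": "similarity-weighted K-NN vote",
        },
        "inputs": {},
        "stages": [],
    }
    for name in ("counts", "soc_mapping", "expression", "gene_network",
                 "tissue_expression", "drug_targets"):
        manifest["inputs"][name] = {"path": str(getattr(cfg, name)),
                                    "sha256": _sha256(getattr(cfg, name))}
    manifest["inputs"]["similarities"] = [
        {"path": str(p), "sha256": _sha256(p)} for p in cfg.similarities]

    state = {}
    try:
        for stage in STAGES:
            t0 = time.perf_counter()
            outputs = _STAGE_FUNCS[stage](cfg, state, outdir)
            entry = {"stage": stage,
                     "seconds": round(time.perf_counter() - t0, 3),
                     "outputs": {}}
            for key, path in outputs.items():
                entry["outputs"][key] = {"path": str(path),
                                         "sha256": _sha256(path)}
            manifest["stages"].append(entry)
            logger.info("stage %s done in %.2fs", stage, entry["seconds"])
    except Exception as exc:
        (outdir / "FAILED").write_text(f"{stage}\n{exc}\n")
        aio.write_json(manifest, outdir / "manifest.json")
        raise PipelineError(stage, exc) from exc

    aio.write_json(manifest, outdir / "manifest.json")
    return manifest


# --------------------------------------------------------------------------
# stage implementations (cfg, state, outdir) -> {output name: path}
# --------------------------------------------------------------------------

def _stage_first(cfg, state, outdir):
    counts = aio.read_counts(cfg.counts)
    # drop unreported AEs / unreported drugs before building the AE network
    counts = counts.loc[counts.sum(axis=1) > 0, counts.sum(axis=0) > 0]
    state["counts"] = counts
    ae_net = ae_profile_similarity(counts)
    nets = [ae_net]
    for path in cfg.similarities:
        src = Path(path).stem.replace("similarity_", "")
        nets.append(aio.read_similarity(path, source=src, stage="first"))
    state["first_stage"] = nets
    out = {}
    for net in nets:
        p = outdir / f"first_{net.source}.tsv"
        aio.write_similarity(net, p)
        out[net.source] = p
    return out


def _stage_impute(cfg, state, outdir):
    anchor = state["first_stage"][0]
    second = [SimilarityNetwork(ids=anchor.ids, matrix=anchor.matrix,
                                source=anchor.source, stage="second")]
    for net in state["first_stage"][1:]:
        second.append(impute_network(anchor, net, cfg.dim_rule))
    state["second_stage"] = second
    out = {}
    for net in second:
        p = outdir / f"second_{net.source}.tsv"
        aio.write_similarity(net, p)
        out[net.source] = p
    return out


def _stage_fuse(cfg, state, outdir):
    fused = snf_fuse(state["second_stage"], cfg.fusion)
    state["fused"] = fused
    p = outdir / "fused.tsv"
    aio.write_similarity(fused, p)
    return {"fused": p}


def _stage_nmf(cfg, state, outdir):
    counts = state["counts"]
    rich = counts.columns[counts.sum(axis=0) >= cfg.min_reports]
    if len(rich) < 3:
        raise ValueError(
            f"only {len(rich)} drug(s) pass the {cfg.min_reports}-report "
            "feedback threshold")
    X = counts[rich]
    X = X.loc[X.sum(axis=1) > 0]
    state["nmf_input"] = X
    out = {}
    if cfg.k == "auto":
        report = select_k(X, cfg.k_range, n_runs=20, seed=[cfg.seed, 10])
        k = report.selected_k
        p = outdir / "stability.json"
        aio.write_json({"k_values": report.k_values,
                        "cophenetic": report.cophenetic,
                        "selected_k": report.selected_k}, p)
        out["stability"] = p
    else:
        k = int(cfg.k)
    model = nmf_factorize(X, k, n_init=cfg.n_init, seed=[cfg.seed, 11])
    state["model"] = model
    pw, ph = outdir / "W.tsv", outdir / "H.tsv"
    aio.write_matrix(model.W, pw)
    aio.write_matrix(model.H, ph)
    out.update({"W": pw, "H": ph})
    return out


def _stage_fractions(cfg, state, outdir):
    frac = abundance_fractions(state["model"])
    state["fractions"] = frac
    p = outdir / "fractions.tsv"
    aio.write_matrix(frac, p)
    return {"fractions": p}


def _stage_observed(cfg, state, outdir):
    observed = assign_clusters(state["fractions"])
    state["observed"] = observed
    p = outdir / "observed_clusters.tsv"
    observed.to_frame().to_csv(p, sep="\t")
    return {"observed_clusters": p}


def _stage_propagate(cfg, state, outdir):
    final = propagate_labels(state["fused"], state["observed"], cfg.K_label)
    state["clusters"] = final
    p = outdir / "clusters.tsv"
    final.to_frame().to_csv(p, sep="\t")
    pv = outdir / "propagation_votes.json"
    aio.write_json(final.votes, pv)
    return {"clusters": p, "votes": pv}


def _stage_enrich(cfg, state, outdir):
    mapping = aio.read_soc_mapping(cfg.soc_mapping)
    table = enrichment_table(state["model"].W, mapping)
    state["enrichment"] = table
    p = outdir / "soc_enrichment.tsv"
    table.to_csv(p, sep="\t", index=False)
    return {"soc_enrichment": p}


def _stage_proximity(cfg, state, outdir):
    graph = aio.read_edge_list(cfg.gene_network)
    net = GeneNetworkDistances(graph)
    expr = aio.read_matrix(cfg.tissue_expression)
    Z = tissue_zscores(expr)
    tissues = top_tissue_genes(Z, n_top=min(cfg.n_top, Z.shape[0]))
    targets = aio.read_drug_targets(cfg.drug_targets)
    table = proximity_heatmap_table(targets, tissues, net,
                                    n_perm=cfg.n_perm, seed=[cfg.seed, 12])
    state["proximity"] = table
    p = outdir / "tissue_proximity.tsv"
    table.to_csv(p, sep="\t", index=False)
    return {"tissue_proximity": p}


def _stage_slda(cfg, state, outdir):
    profile = aio.read_matrix(cfg.expression)
    clusters = state["clusters"]
    k = state["model"].k
    merge = cfg.merge_control and k >= 4
    results = pairwise_discriminant_sets(profile, clusters,
                                         merge_control=merge)
    rows = []
    for res in results:
        for g in res.path.genes:
            rows.append({"pair": f"{res.pair[0]}-{res.pair[1]}",
                         "gene": g, "beta": float(res.beta[g]),
                         "selected": g in set(res.nonzero_genes)})
    p = outdir / "slda_genes.tsv"
    pd.DataFrame(rows).to_csv(p, sep="\t", index=False)
    ph = outdir / "slda_heatmap.tsv"
    heatmap_table(profile, clusters, results).to_csv(ph, sep="\t",
                                                     index=False)
    state["slda"] = results
    return {"slda_genes": p, "slda_heatmap": ph}


_STAGE_FUNCS = {
    "first_stage_networks": _stage_first,
    "imputation": _stage_impute,
    "fusion": _stage_fuse,
    "nmf": _stage_nmf,
    "abundance_fractions": _stage_fractions,
    "observed_clusters": _stage_observed,
    "label_propagation": _stage_propagate,
    "soc_enrichment": _stage_enrich,
    "tissue_proximity": _stage_proximity,
    "slda_discriminant": _stage_slda,
}
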