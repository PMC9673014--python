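"""TSV readers and writers for every pipeline input/output format.

All formats are plain tab-separated text with header identifiers:

* counts: AE rows x drug columns, nonnegative integers
* similarity: square matrix with matching row/column identifiers
* edge list: two gene-id columns, undirected, no header required
* SOC map: two columns (AE id, SOC category)
* drug targets: two columns (drug id, comma-separated gene ids)
* gene x tissue expression: gene rows, tissue columns
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .types import SimilarityNetwork, check_counts


def read_counts(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return check_counts(df)


def write_counts(counts: pd.DataFrame, path) -> None:
    check_counts(counts)
    counts.astype(int).to_csv(path, sep="\t")


def read_similarity(path, source: str = "unknown",
                    stage: str = "first") -> SimilarityNetwork:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return SimilarityNetwork.from_frame(df, source=source, stage=stage)


def write_similarity(net: SimilarityNetwork, path) -> None:
    net.to_frame().to_csv(path, sep="\t")


def read_matrix(path) -> pd.DataFrame:
    """Generic labeled real matrix (expression, fingerprints, tissue means)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def write_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t")


def read_edge_list(path) -> nx.Graph:
    g = nx.Graph()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            a, b = line.split("\t")[:2]
            if a == b:
                continue  # the gene network is a simple graph
            g.add_edge(a, b)
    return g


def write_edge_list(graph: nx.Graph, path) -> None:
    with open(path, "w") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in graph.edges):
            fh.write(f"{a}\t{b}\n")


def read_soc_mapping(path) -> dict:
    df = pd.read_csv(path, sep="\t", header=None, names=["ae", "soc"], dtype=str,
                     comment="#")
    if df["ae"].duplicated().any():
        dup = df["ae"][df["ae"].duplicated()].iloc[0]
        raise ValueError(f"AE {dup!r} mapped to more than one SOC category")
    return dict(zip(df["ae"], df["soc"]))


def write_soc_mapping(mapping: dict, path) -> None:
    with open(path, "w") as fh:
        for ae in sorted(mapping):
            fh.write(f"{ae}\t{mapping[ae]}\n")


def read_drug_targets(path) -> dict:
    targets = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            drug, genes = line.split("\t")[:2]
            targets[drug] = set(genes.split(","))
    return targets


def write_drug_targets(targets: dict, path) -> None:
    with open(path, "w") as fh:
        for drug in sorted(targets):
            fh.write(f"{drug}\t{','.join(sorted(targets[drug]))}\n")


def write_json(obj, path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, set):
            return sorted(o)
        if isinstance(o, Path):
            return str(o)
        raise TypeError(f"cannot serialize {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, default=_default)


def read_json(path):
    with open(path) as fh:
        return json.load(fh)
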