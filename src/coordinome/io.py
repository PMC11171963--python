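"""Readers and writers for the pipeline's plain-text formats.

Expression matrices travel as TSV (first column the gene id, sample
columns named ``<condition>_<replicate>``); gene sets as one id per line;
correlation tables as (optionally gzipped) TSV; networks as SIF
(``geneA pos geneB``) or GraphML with r edge weights; everything else as
JSON.
"""

from __future__ import annotations

import gzip
import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd


def read_expression_tsv(path) -> pd.DataFrame:
    matrix = pd.read_csv(path, sep="\t", index_col=0)
    matrix.index.name = "gene"
    if matrix.index.duplicated().any():
        raise ValueError("duplicate gene ids in expression matrix")
    if not np.isfinite(matrix.to_numpy(dtype=float)).all():
        raise ValueError("expression matrix contains non-finite values")
    return matrix


def write_expression_tsv(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t")


def read_gene_set(path) -> list:
    with open(path) as fh:
        genes = [line.strip() for line in fh if line.strip()]
    return genes


def write_gene_set(genes, path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in sorted(genes)))


def write_correlation_table(table: pd.DataFrame, path) -> None:
    path = str(path)
    if path.endswith(".gz"):
        with gzip.open(path, "wt") as fh:
            table.to_csv(fh, sep="\t", index=False)
    else:
        table.to_csv(path, sep="\t", index=False)


def read_correlation_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    required = {"gene_a", "gene_b", "r"}
    if not required <= set(table.columns):
        raise ValueError(f"correlation table must have columns {sorted(required)}")
    return table


def write_sif(graph: nx.Graph, path, relation: str = "pos") -> None:
    with open(path, "w") as fh:
        for u, v in graph.edges():
            fh.write(f"{u}\t{relation}\t{v}\n")
        for node in nx.isolates(graph):
            fh.write(f"{node}\n")


def read_sif(path) -> nx.Graph:
    g = nx.Graph()
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) == 1:
                g.add_node(parts[0])
            else:
                source, _, *targets = parts
                for t in targets:
                    g.add_edge(source, t)
    return g


def write_graphml(graph: nx.Graph, path) -> None:
    g = graph.copy()
    g.graph.pop("excluded", None)  # lists are not valid GraphML attributes
    nx.write_graphml(g, path)


def read_graph(path) -> nx.Graph:
    path = str(path)
    if path.endswith(".sif"):
        return read_sif(path)
    if path.endswith(".graphml"):
        return nx.read_graphml(path)
    return nx.read_edgelist(path)


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        return super().default(obj)


def write_json(data, path) -> None:
    with open(path, "w") as fh:
        json.dump(data, fh, indent=2, cls=_NumpyEncoder)
        fh.write("\n")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)
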