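"""File formats: TSV dialects, GraphML export, JSON summaries.

All tabular artefacts are tab-separated text with a header row;
missing expression values are written as the literal ``NA``.  Graphs
are exchanged as GraphML with stable attribute names (``r``, ``sign``,
``kind``, ``category``, ``evidence``, ...).  Malformed inputs raise
errors naming the offending file and rule.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .hierarchy import HierarchyConfig, NodeHierarchy
from .network import GeneNetwork
from .preprocess import ExpressionTable

__all__ = [
    "write_expression",
    "read_expression",
    "write_sample_sheet",
    "read_sample_sheet",
    "write_edgelist",
    "read_edgelist",
    "write_hierarchy",
    "read_hierarchy",
    "write_membership",
    "read_membership",
    "write_target_table",
    "read_target_table",
    "write_graphml",
    "read_graphml",
    "write_json",
]

_NA = "NA"


def write_expression(
    table: ExpressionTable, path, samples_path=None
) -> None:
    """Write genes x samples TSV (first column the gene id, ``NA`` for
    missing); optionally the sample sheet alongside."""
    df = table.values.copy()
    df.index.name = df.index.name or "gene"
    df.to_csv(path, sep="\t", na_rep=_NA)
    if samples_path is not None:
        write_sample_sheet(table.groups, samples_path)


def read_expression(path, samples_path, modality: str = "mRNA") -> ExpressionTable:
    values = pd.read_csv(path, sep="\t", index_col=0, na_values=[_NA])
    if values.index.has_duplicates:
        dup = values.index[values.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate gene id {dup!r}")
    groups = read_sample_sheet(samples_path)
    return ExpressionTable(values, groups, modality=modality)


def write_sample_sheet(groups: pd.Series, path) -> None:
    pd.DataFrame({"sample": groups.index, "group": groups.values}).to_csv(
        path, sep="\t", index=False
    )


def read_sample_sheet(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    for col in ("sample", "group"):
        if col not in df.columns:
            raise ValueError(f"{path}: sample sheet needs a '{col}' column")
    return pd.Series(df["group"].values, index=df["sample"].values, name="group")


def write_edgelist(net: GeneNetwork, path) -> None:
    rows = [
        (u, v, d.get("r", np.nan), d.get("sign", 1))
        for u, v, d in net.graph.edges(data=True)
    ]
    pd.DataFrame(rows, columns=["gene_a", "gene_b", "r", "sign"]).to_csv(
        path, sep="\t", index=False
    )


def read_edgelist(path, threshold: float | None = None) -> GeneNetwork:
    df = pd.read_csv(path, sep="\t")
    for col in ("gene_a", "gene_b"):
        if col not in df.columns:
            raise ValueError(f"{path}: edge list needs a '{col}' column")
    g = nx.Graph()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        if row.gene_a == row.gene_b:
            raise ValueError(f"{path}:{i}: self-loop on {row.gene_a!r}")
        attrs = {}
        if hasattr(row, "r"):
            attrs["r"] = float(row.r)
            attrs["sign"] = int(getattr(row, "sign", 1 if row.r >= 0 else -1))
        g.add_edge(row.gene_a, row.gene_b, **attrs)
    if threshold is None:
        rs = [abs(d["r"]) for _, _, d in g.edges(data=True) if "r" in d]
        threshold = min(rs) if rs else 0.0
    return GeneNetwork(graph=g, threshold=float(threshold))


def write_hierarchy(h: NodeHierarchy, path) -> None:
    h.table.to_csv(path, sep="\t")


def read_hierarchy(path, config: HierarchyConfig | None = None) -> NodeHierarchy:
    df = pd.read_csv(path, sep="\t", index_col=0)
    for col in ("k0", "k1", "category"):
        if col not in df.columns:
            raise ValueError(f"{path}: hierarchy table needs a '{col}' column")
    return NodeHierarchy(df, config or HierarchyConfig())


def write_membership(labels: dict, path) -> None:
    pd.DataFrame(
        {"gene": list(labels), "community": list(labels.values())}
    ).to_csv(path, sep="\t", index=False)


def read_membership(path) -> dict:
    df = pd.read_csv(path, sep="\t")
    for col in ("gene", "community"):
        if col not in df.columns:
            raise ValueError(f"{path}: membership table needs a '{col}' column")
    return dict(zip(df["gene"], df["community"]))


def write_target_table(targets: pd.DataFrame, path) -> None:
    targets.to_csv(path, sep="\t", index=False)


def read_target_table(path) -> pd.DataFrame:
    from .mirna import validate_target_table

    df = pd.read_csv(path, sep="\t")
    try:
        return validate_target_table(df)
    except ValueError as err:
        raise ValueError(f"{path}: {err}") from err


def write_graphml(graph: nx.Graph | GeneNetwork, path) -> None:
    g = graph.graph if isinstance(graph, GeneNetwork) else graph
    nx.write_graphml(g, path, named_key_ids=True)


def read_graphml(path) -> nx.Graph:
    return nx.read_graphml(path)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (set, tuple)):
        return sorted(obj) if isinstance(obj, set) else list(obj)
    if isinstance(obj, Path):
        return str(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def write_json(payload: dict, path) -> None:
    Path(path).write_text(
        json.dumps(payload, indent=2, sort_keys=True, default=_json_default) + "\n"
    )
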