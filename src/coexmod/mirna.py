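"""miRNA integration with gene coexpression networks.

Differentially expressed miRNAs are joined to the gene networks through
a user-supplied target table whose rows are (miRNA, gene, evidence)
with evidence either ``validated`` (experimentally confirmed) or
``predicted``.  Two integrations mirror the analysis conventions:

* DE networks — keep every validated interaction whose gene is in the
  network, but admit predicted interactions only when the gene is
  high-hierarchy (hub / VIP / high-hub);
* CO networks — restrict the gene side to high-hierarchy genes and
  their mutual edges, admitting both evidence levels there.

"Abundant" miRNAs are those whose linear-scale mean expression exceeds
a configurable multiple (default 30x) of the average over all valid
miRNAs, in both sample groups.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd

from .hierarchy import NodeHierarchy, high_hierarchy_set
from .network import GeneNetwork
from .preprocess import ExpressionTable

__all__ = [
    "validate_target_table",
    "flag_abundant",
    "integrate_de",
    "integrate_co_hh",
]

EVIDENCE_LEVELS = ("validated", "predicted")


def validate_target_table(targets: pd.DataFrame) -> pd.DataFrame:
    """Check and de-duplicate a miRNA-target table.

    Requires columns mirna, gene, evidence; evidence restricted to
    ``validated``/``predicted``; duplicate (mirna, gene, evidence)
    triples are dropped.
    """
    required = {"mirna", "gene", "evidence"}
    missing = required - set(targets.columns)
    if missing:
        raise ValueError(f"target table missing columns: {sorted(missing)}")
    bad = set(targets["evidence"]) - set(EVIDENCE_LEVELS)
    if bad:
        raise ValueError(f"unknown evidence levels: {sorted(bad)}")
    return targets.drop_duplicates(subset=["mirna", "gene", "evidence"])


def flag_abundant(
    mirna_table: ExpressionTable, factor: float = 30.0
) -> set[str]:
    """miRNAs whose linear mean is >= ``factor`` x the global average.

    The table holds log2 intensities; means are taken on the linear
    scale.  The baseline is the average of the per-miRNA means within
    each group, and the rule must hold in BOTH groups.
    """
    flagged: set[str] | None = None
    for group in mirna_table.group_names:
        linear = 2.0 ** mirna_table.group_values(group)
        per_mirna = linear.mean(axis=1, skipna=True)
        baseline = per_mirna.mean(skipna=True)
        hits = set(per_mirna.index[per_mirna >= factor * baseline])
        flagged = hits if flagged is None else flagged & hits
    return flagged or set()


def _mirna_directions(de_mirnas) -> dict:
    if isinstance(de_mirnas, dict):
        return dict(de_mirnas)
    return {m: "" for m in de_mirnas}


def _base_gene_graph(net: GeneNetwork, genes=None) -> nx.Graph:
    g = net.graph
    if genes is not None:
        g = g.subgraph([n for n in genes if n in g])
    out = nx.Graph()
    out.add_nodes_from((n, {"kind": "gene"}) for n in g.nodes())
    out.add_edges_from(
        (u, v, {"kind": "coexpression", **d}) for u, v, d in g.edges(data=True)
    )
    return out


def _annotate(
    g: nx.Graph,
    hierarchy: NodeHierarchy | None,
    directions: dict,
    abundant: set | None,
) -> None:
    if hierarchy is not None:
        cats = hierarchy.table["category"]
        for n in g.nodes():
            if g.nodes[n].get("kind") == "gene" and n in cats.index:
                g.nodes[n]["category"] = cats[n]
    for n in g.nodes():
        if g.nodes[n].get("kind") == "mirna":
            g.nodes[n]["direction"] = directions.get(n, "")
            if abundant is not None:
                g.nodes[n]["abundant"] = n in abundant


def _add_target_edges(
    g: nx.Graph,
    targets: pd.DataFrame,
    mirnas: set,
    allowed_gene: callable,
) -> None:
    for row in targets.itertuples(index=False):
        if row.mirna not in mirnas:
            continue
        if row.gene not in g or g.nodes[row.gene].get("kind") != "gene":
            continue
        if not allowed_gene(row.gene, row.evidence):
            continue
        if g.has_edge(row.mirna, row.gene):
            # validated wins over predicted for the same pair
            if g.edges[row.mirna, row.gene]["evidence"] == "validated":
                continue
        g.add_node(row.mirna, kind="mirna")
        g.add_edge(row.mirna, row.gene, kind="target", evidence=row.evidence)


def _drop_unconnected_mirnas(g: nx.Graph) -> None:
    drop = [
        n for n, d in g.nodes(data=True)
        if d.get("kind") == "mirna" and g.degree(n) == 0
    ]
    g.remove_nodes_from(drop)


def integrate_de(
    net: GeneNetwork,
    de_genes,
    hierarchy: NodeHierarchy,
    de_mirnas,
    targets: pd.DataFrame,
    abundant: set | None = None,
) -> nx.Graph:
    """Join DE miRNAs to the DE gene network.

    Inclusion rules: (i) every validated interaction whose gene is a DE
    gene present in the network; (ii) predicted interactions only for
    high-hierarchy genes.  miRNAs with no surviving interaction are
    dropped.  Gene nodes keep their hierarchy category; miRNA nodes
    carry direction and, optionally, the abundant flag.
    """
    targets = validate_target_table(targets)
    directions = _mirna_directions(de_mirnas)
    de_set = set(de_genes)
    hh = set(high_hierarchy_set(hierarchy))
    g = _base_gene_graph(net)

    def allowed(gene, evidence) -> bool:
        if gene not in de_set:
            return False
        return evidence == "validated" or gene in hh

    _add_target_edges(g, targets, set(directions), allowed)
    _drop_unconnected_mirnas(g)
    _annotate(g, hierarchy, directions, abundant)
    return g


def integrate_co_hh(
    net: GeneNetwork,
    hierarchy: NodeHierarchy,
    de_mirnas,
    targets: pd.DataFrame,
    abundant: set | None = None,
) -> nx.Graph:
    """Join DE miRNAs to the high-hierarchy subnetwork of a CO network.

    The gene side is restricted to HH genes and the edges among them;
    both validated and predicted interactions are admitted for those
    genes.  miRNAs targeting only non-HH genes are absent.
    """
    targets = validate_target_table(targets)
    directions = _mirna_directions(de_mirnas)
    hh = set(high_hierarchy_set(hierarchy))
    g = _base_gene_graph(net, genes=hh)

    _add_target_edges(g, targets, set(directions), lambda gene, ev: True)
    _drop_unconnected_mirnas(g)
    _annotate(g, hierarchy, directions, abundant)
    return g
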