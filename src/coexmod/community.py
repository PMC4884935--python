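"""Community structure: Louvain partitions, mixing matrix, coarse graining.

Communities are found by Louvain modularity optimisation (greedy local
moves plus aggregation, best of several seeded restarts).  The quality
of a partition is Newman-Girvan modularity

    Q = sum_a ( E_aa / L  -  (d_a / 2L)^2 )

with E_aa the within-community edge count, d_a the total degree in
community a and L the edge count — evaluated here in exact rational
arithmetic.  The inter-community organisation is summarised by the
mixing matrix: E_ab edges between communities a and b, normalised to a
connection weight W_ab = E_ab / (|a||b|), the probability that a random
(a, b) node pair is linked; normalising by the size product removes the
bias toward large communities.  Contracting each community to a single
node with W_ab edge weights yields the coarse-grained community
structure (CGCS).
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import networkx as nx
import numpy as np
import pandas as pd

from .network import CorrelationMatrix, GeneNetwork, build_network, connectivity
from .preprocess import ExpressionTable

__all__ = [
    "CommunityPartition",
    "MixingMatrix",
    "louvain",
    "modularity",
    "mixing_matrix",
    "coarse_grain",
    "robustness_sweep",
    "community_subnetworks",
]


def _graph_of(net) -> nx.Graph:
    return net.graph if isinstance(net, GeneNetwork) else net


def _community_labels(labels_or_partition) -> dict:
    if isinstance(labels_or_partition, CommunityPartition):
        return labels_or_partition.labels
    return dict(labels_or_partition)


@dataclass
class CommunityPartition:
    """Node -> community labels with the partition's modularity Q.

    Labels are 'A', 'B', 'C', ... in decreasing community size (ties
    broken by smallest member id), so community A is always the
    largest.
    """

    labels: dict
    q: float
    sizes: dict
    seed: int

    @property
    def n_communities(self) -> int:
        return len(self.sizes)

    def members(self, label) -> list:
        return [n for n, c in self.labels.items() if c == label]


def _relabel_by_size(communities: list[set]) -> dict:
    ordered = sorted(
        communities, key=lambda c: (-len(c), min(str(n) for n in c))
    )
    labels: dict = {}
    for i, comm in enumerate(ordered):
        name = _alpha_label(i)
        for node in comm:
            labels[node] = name
    return labels


def _alpha_label(i: int) -> str:
    # A..Z, then AA, AB, ...
    name = ""
    i += 1
    while i:
        i, rem = divmod(i - 1, 26)
        name = chr(ord("A") + rem) + name
    return name


def modularity(net, labels, exact: bool = False):
    """Newman-Girvan modularity of a labelled partition.

    Evaluated with Fraction arithmetic on the integer edge/degree
    counts, so equal partitions give bit-identical Q.  ``exact=True``
    returns the Fraction itself.
    """
    g = _graph_of(net)
    labels = _community_labels(labels)
    if set(labels) != set(g.nodes()):
        raise ValueError("labels must cover exactly the network's nodes")
    L = g.number_of_edges()
    if L == 0:
        raise ValueError("modularity undefined for an edgeless graph")
    e_within: dict = {}
    degree_sum: dict = {}
    for node in g.nodes():
        degree_sum[labels[node]] = degree_sum.get(labels[node], 0) + g.degree(node)
    for u, v in g.edges():
        if labels[u] == labels[v]:
            e_within[labels[u]] = e_within.get(labels[u], 0) + 1
    q = Fraction(0)
    for comm, d in degree_sum.items():
        q += Fraction(e_within.get(comm, 0), L) - Fraction(d, 2 * L) ** 2
    return q if exact else float(q)


def louvain(
    net, seed: int = 0, n_restarts: int = 10, resolution: float = 1.0
) -> CommunityPartition:
    """Louvain community detection, best of ``n_restarts`` seeded runs.

    Each restart shuffles the node-visit order with a seed derived from
    ``seed``; the partition with the highest (exact) modularity wins,
    so the result is deterministic given the seed.
    """
    g = _graph_of(net)
    if g.number_of_nodes() == 0:
        raise ValueError("cannot partition an empty graph")
    if g.number_of_edges() == 0:
        raise ValueError("cannot partition an edgeless graph")
    best: tuple[Fraction, list[set]] | None = None
    for i in range(n_restarts):
        comms = [
            set(c)
            for c in nx.community.louvain_communities(
                g, weight=None, resolution=resolution, seed=seed + i
            )
        ]
        labels = {n: j for j, c in enumerate(comms) for n in c}
        q = modularity(g, labels, exact=True)
        if best is None or q > best[0]:
            best = (q, comms)
    q, comms = best
    labels = _relabel_by_size(comms)
    sizes: dict = {}
    for c in sorted(set(labels.values())):
        sizes[c] = sum(1 for v in labels.values() if v == c)
    return CommunityPartition(labels=labels, q=float(q), sizes=sizes, seed=seed)


@dataclass
class MixingMatrix:
    """Community-pair edge counts and normalised connection weights.

    ``e`` is symmetric with within-community counts on the diagonal;
    ``w`` holds W_ab = E_ab/(|a||b|) off-diagonal (diagonal 0 — the
    weight is defined for distinct pairs).  ``node_strength`` is each
    community's summed inter-community weight, its total probability of
    connecting to other communities.
    """

    e: pd.DataFrame
    w: pd.DataFrame
    sizes: pd.Series

    @property
    def node_strength(self) -> pd.Series:
        return self.w.sum(axis=1)

    def within_density(self) -> pd.Series:
        """2 E_aa / (|a| (|a|-1)); 0 for singleton communities."""
        dens = {}
        for c in self.sizes.index:
            n = self.sizes[c]
            dens[c] = 2.0 * self.e.loc[c, c] / (n * (n - 1)) if n > 1 else 0.0
        return pd.Series(dens)

    def check_conservation(self, n_edges: int) -> bool:
        e = self.e.to_numpy()
        total = int(np.triu(e).sum())
        return total == n_edges


def mixing_matrix(net, partition) -> MixingMatrix:
    """Count edges within and between communities and normalise.

    Edge conservation holds exactly: the diagonal plus the upper
    triangle of ``e`` sums to the graph's edge count.
    """
    g = _graph_of(net)
    labels = _community_labels(partition)
    comms = sorted(set(labels.values()))
    sizes = pd.Series(
        {c: sum(1 for v in labels.values() if v == c) for c in comms}
    )
    e = pd.DataFrame(0, index=comms, columns=comms, dtype=int)
    for u, v in g.edges():
        a, b = labels[u], labels[v]
        e.loc[a, b] += 1
        if a != b:
            e.loc[b, a] += 1
    w = pd.DataFrame(0.0, index=comms, columns=comms)
    for a in comms:
        for b in comms:
            if a != b:
                w.loc[a, b] = e.loc[a, b] / (sizes[a] * sizes[b])
    return MixingMatrix(e=e, w=w, sizes=sizes)


def coarse_grain(net, partition, hh_genes=None) -> nx.Graph:
    """Contract communities into single nodes: the CGCS graph.

    Node attributes: ``size`` (member count) and ``within_density``;
    edges weighted by W_ab (absent when W_ab = 0).  With ``hh_genes``
    given, the graph is restricted to communities containing at least
    one of those genes.
    """
    labels = _community_labels(partition)
    mm = mixing_matrix(net, partition)
    keep = list(mm.sizes.index)
    if hh_genes is not None:
        hh = set(hh_genes)
        keep = [
            c for c in keep
            if any(labels[n] == c for n in labels if n in hh)
        ]
    dens = mm.within_density()
    g = nx.Graph()
    for c in keep:
        g.add_node(c, size=int(mm.sizes[c]), within_density=float(dens[c]))
    for i, a in enumerate(keep):
        for b in keep[i + 1:]:
            w = float(mm.w.loc[a, b])
            if w > 0:
                g.add_edge(a, b, weight=w, n_edges=int(mm.e.loc[a, b]))
    return g


def robustness_sweep(
    corr: CorrelationMatrix,
    tau_values,
    seed: int = 0,
    reference_tau: float | None = None,
    n_restarts: int = 10,
) -> pd.DataFrame:
    """Community structure across a range of thresholds.

    For each tau: network size, edge count, modularity, community count
    and the ARI between that partition and the reference partition
    (restricted to shared nodes).  The reference is the partition at
    ``reference_tau`` (default: the smallest tau).  Rows whose network
    is empty are flagged and carry NaNs.
    """
    from sklearn.metrics import adjusted_rand_score

    taus = sorted(float(t) for t in tau_values)
    ref_tau = float(reference_tau) if reference_tau is not None else taus[0]
    ref_net = build_network(corr, ref_tau)
    ref_labels = (
        louvain(ref_net, seed=seed, n_restarts=n_restarts).labels
        if ref_net.n_edges
        else {}
    )
    rows = []
    for tau in taus:
        net = build_network(corr, tau)
        if net.n_edges == 0:
            rows.append(
                {"tau": tau, "n_nodes": 0, "n_edges": 0, "q": np.nan,
                 "n_communities": 0, "ari": np.nan, "empty": True}
            )
            continue
        part = louvain(net, seed=seed, n_restarts=n_restarts)
        shared = sorted(set(part.labels) & set(ref_labels))
        if tau == ref_tau:
            ari = 1.0
        elif len(shared) >= 2:
            ari = float(
                adjusted_rand_score(
                    [ref_labels[n] for n in shared],
                    [part.labels[n] for n in shared],
                )
            )
        else:
            ari = np.nan
        rows.append(
            {"tau": tau, "n_nodes": net.n_nodes, "n_edges": net.n_edges,
             "q": part.q, "n_communities": part.n_communities,
             "ari": ari, "empty": False}
        )
    return pd.DataFrame(rows)


def community_subnetworks(
    table: ExpressionTable,
    partition,
    tau: float,
    min_size: int = 100,
    group: str | None = None,
) -> pd.DataFrame:
    """Rebuild each large community's own coexpression network.

    Only communities with at least ``min_size`` member genes qualify;
    each qualifying community's genes are re-correlated (Pearson, same
    sample group) and thresholded at the parent network's tau.  Reports
    N, L and k = 2L/N per community.
    """
    from .network import pearson_matrix

    labels = _community_labels(partition)
    comms = sorted(set(labels.values()))
    rows = []
    for c in comms:
        genes = [g for g, lab in labels.items() if lab == c]
        if len(genes) < min_size:
            continue
        sub_table = table.with_values(table.values.loc[genes])
        corr = pearson_matrix(sub_table, group=group)
        net = build_network(corr, tau)
        rows.append(
            {"community": c, "n_genes": len(genes), "n_nodes": net.n_nodes,
             "n_edges": net.n_edges, "connectivity": connectivity(net)}
        )
    return pd.DataFrame(
        rows,
        columns=["community", "n_genes", "n_nodes", "n_edges", "connectivity"],
    )
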