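"""Concentric node degrees and hub / VIP / high-hub categorisation.

Each node v is scored by its usual degree k0 and its first-level
concentric degree k1: the number of edges leaving v's immediate
neighbourhood, i.e. edges joining a node at breadth-first distance 1
from v to a node at distance 2 (edges internal to ring 1 do not leave
the neighbourhood and are not counted).

Categories, following the k0-vs-k1 scatter convention:

* hub      - k0 at or above a high quantile of the degree distribution
             (and strictly above the median, so uniform-degree graphs
             declare no hubs);
* VIP      - low k0 (at or below a low quantile) but connected
             (essentially) only to hubs;
* high-hub - a hub whose k1 is also at or above a high quantile: a hub
             wired to other highly connected nodes.

Precedence is high-hub > hub > VIP; the union of the three is the
high-hierarchy (HH) gene set.  Quantile cutoffs are configuration, not
constants — the decision boundary is a property of each network's
degree cloud.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .network import GeneNetwork

__all__ = [
    "HierarchyConfig",
    "NodeHierarchy",
    "concentric_degree",
    "classify_nodes",
    "high_hierarchy_set",
]

CATEGORIES = ("none", "hub", "VIP", "high-hub")


@dataclass
class HierarchyConfig:
    """Quantile cutoffs for the k0/k1 categorisation.

    ``hub_quantile``/``highhub_k1_quantile`` are upper quantiles of k0
    and k1 over the network's nodes; ``vip_max_quantile`` bounds a
    VIP's k0 from above; ``vip_neighbor_hub_fraction`` is the minimum
    fraction of a VIP's neighbours that must be hubs (1.0 = all).
    """

    hub_quantile: float = 0.90
    highhub_k1_quantile: float = 0.90
    vip_max_quantile: float = 0.50
    vip_neighbor_hub_fraction: float = 1.0

    def __post_init__(self) -> None:
        for name in ("hub_quantile", "highhub_k1_quantile", "vip_max_quantile",
                     "vip_neighbor_hub_fraction"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1]")
        if self.vip_max_quantile >= self.hub_quantile:
            raise ValueError("vip_max_quantile must be below hub_quantile")


@dataclass
class NodeHierarchy:
    """Per-node k0, k1 and category (DataFrame indexed by gene id)."""

    table: pd.DataFrame
    config: HierarchyConfig

    def nodes_in(self, category: str) -> list:
        return list(self.table.index[self.table["category"] == category])


def _graph_of(net: GeneNetwork | nx.Graph) -> nx.Graph:
    return net.graph if isinstance(net, GeneNetwork) else net


def concentric_degree(net: GeneNetwork | nx.Graph, node, level: int = 1) -> int:
    """First-level concentric degree: edges from ring 1 to ring 2 of *node*.

    Rings are breadth-first distance shells around the node.  Only
    level 1 is supported (the k0/k1 plane is what the categorisation
    uses).
    """
    if level != 1:
        raise NotImplementedError("only the first concentric level is defined")
    g = _graph_of(net)
    if node not in g:
        raise KeyError(f"node {node!r} not in network")
    ring1 = set(g[node])
    ring2 = {
        w for u in ring1 for w in g[u] if w != node and w not in ring1
    }
    return sum(1 for u in ring1 for w in g[u] if w in ring2)


def classify_nodes(
    net: GeneNetwork | nx.Graph, config: HierarchyConfig | None = None
) -> NodeHierarchy:
    """Compute k0/k1 for every node and assign hierarchy categories.

    Rules (see module docstring): hub requires k0 >= the hub quantile
    cutoff AND k0 > median(k0); VIP requires k0 <= the VIP cutoff and a
    hub fraction among neighbours >= the configured minimum; high-hub
    requires hub status and k1 >= the k1 quantile cutoff.  Invariant
    under node relabeling.
    """
    config = config or HierarchyConfig()
    g = _graph_of(net)
    nodes = list(g.nodes())
    if not nodes:
        return NodeHierarchy(
            pd.DataFrame(columns=["k0", "k1", "category"]), config
        )
    k0 = np.array([g.degree(v) for v in nodes], dtype=float)
    k1 = np.array([concentric_degree(g, v) for v in nodes], dtype=float)

    hub_cut = np.quantile(k0, config.hub_quantile)
    median_k0 = np.median(k0)
    is_hub = (k0 >= hub_cut) & (k0 > median_k0)
    hub_nodes = {v for v, h in zip(nodes, is_hub) if h}

    k1_cut = np.quantile(k1, config.highhub_k1_quantile)
    is_highhub = is_hub & (k1 >= k1_cut) & (k1 > 0)

    vip_cut = np.quantile(k0, config.vip_max_quantile)
    is_vip = np.zeros(len(nodes), dtype=bool)
    for i, v in enumerate(nodes):
        if is_hub[i] or k0[i] > vip_cut or k0[i] == 0:
            continue
        neigh = list(g[v])
        frac = sum(1 for u in neigh if u in hub_nodes) / len(neigh)
        is_vip[i] = frac >= config.vip_neighbor_hub_fraction

    category = np.full(len(nodes), "none", dtype=object)
    category[is_vip] = "VIP"
    category[is_hub] = "hub"
    category[is_highhub] = "high-hub"

    table = pd.DataFrame(
        {"k0": k0.astype(int), "k1": k1.astype(int), "category": category},
        index=pd.Index(nodes, name="gene"),
    )
    return NodeHierarchy(table, config)


def high_hierarchy_set(h: NodeHierarchy) -> list:
    """High-hierarchy (HH) genes: hubs, VIPs and high-hubs, in stable
    table order, duplicate-free."""
    mask = h.table["category"] != "none"
    return list(dict.fromkeys(h.table.index[mask]))
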