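import networkx as nx
import numpy as np
import pandas as pd
import pytest

from coexmod import ExpressionTable, SyntheticConfig, generate_expression


def make_table(values, groups=None, modality="mRNA", genes=None) -> ExpressionTable:
    """Small ExpressionTable from a 2-D array; half the columns per group."""
    arr = np.asarray(values, dtype=float)
    n_genes, n_samples = arr.shape
    genes = genes or [f"g{i}" for i in range(n_genes)]
    samples = [f"s{j}" for j in range(n_samples)]
    if groups is None:
        half = n_samples // 2
        groups = ["CT"] * half + ["DS"] * (n_samples - half)
    df = pd.DataFrame(arr, index=genes, columns=samples)
    return ExpressionTable(df, pd.Series(groups, index=samples), modality=modality)


@pytest.fixture
def modular_table():
    """300 genes, 3 planted modules of 50, strong factors, no DE."""
    cfg = SyntheticConfig(
        n_genes=300, module_sizes=(50, 50, 50), factor_strength=0.9,
        noise_sd=0.3, de_fraction=0.0, seed=1,
    )
    return generate_expression(cfg)


@pytest.fixture
def path_graph():
    g = nx.Graph()
    g.add_edges_from([("a", "b"), ("b", "c"), ("c", "d")])
    return g


@pytest.fixture
def star_graph():
    g = nx.star_graph(10)
    return nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes()})


def random_graph(rng: np.random.Generator, n_max: int = 30, p=None) -> nx.Graph:
    n = int(rng.integers(3, n_max + 1))
    p = p if p is not None else float(rng.uniform(0.1, 0.6))
    return nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
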