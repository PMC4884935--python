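"""Per-group Pearson coexpression networks.

A gene coexpression network (GCN) links two genes when the absolute
Pearson correlation of their expression profiles within one sample
group reaches a hard threshold tau.  The threshold is chosen on a grid
so that (a) the giant component holds a required fraction of the
non-isolated nodes and (b) the community structure is stable under
small threshold perturbations (adjusted Rand index of Louvain
partitions at tau +/- delta).  Network connectivity is k = 2L/N, and
scale-free status is assessed by a discrete power-law maximum-
likelihood fit with the Kolmogorov-Smirnov xmin scan.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import optimize, special
from sklearn.metrics import adjusted_rand_score

from .preprocess import ExpressionTable

__all__ = [
    "CorrelationMatrix",
    "GeneNetwork",
    "PowerLawFit",
    "pearson_matrix",
    "build_network",
    "select_threshold",
    "connectivity",
    "scalefree_test",
    "fit_discrete_powerlaw",
    "sample_discrete_powerlaw",
]

#: Pairs sharing fewer complete samples than this have undefined r.
MIN_SHARED_SAMPLES = 6


@dataclass
class CorrelationMatrix:
    """Gene x gene Pearson correlations with per-pair sample counts.

    ``r`` is symmetric with unit diagonal; entries whose complete-pair
    count falls below ``min_shared`` are NaN (undefined) and never
    create edges.
    """

    r: pd.DataFrame
    n_shared: pd.DataFrame
    min_shared: int = MIN_SHARED_SAMPLES
    group: str | None = None

    @property
    def gene_ids(self) -> pd.Index:
        return self.r.index

    def max_abs(self) -> float:
        """Largest off-diagonal |r| (ignoring undefined pairs)."""
        arr = np.abs(self.r.to_numpy(copy=True))
        np.fill_diagonal(arr, np.nan)
        return float(np.nanmax(arr)) if np.isfinite(arr).any() else 0.0


@dataclass
class GeneNetwork:
    """Undirected thresholded coexpression graph.

    Edges carry the correlation (``r``) and its sign; isolated genes are
    not part of the node set.  ``group`` / ``gene_set`` record
    provenance (e.g. CT vs DS, DE vs CO).
    """

    graph: nx.Graph
    threshold: float
    group: str | None = None
    gene_set: str | None = None

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def summary(self) -> dict:
        return {
            "group": self.group,
            "gene_set": self.gene_set,
            "threshold": self.threshold,
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "connectivity": connectivity(self),
        }


def pearson_matrix(
    table: ExpressionTable,
    group: str | None = None,
    min_shared: int = MIN_SHARED_SAMPLES,
) -> CorrelationMatrix:
    """Pairwise-complete Pearson correlation within one sample group.

    Uses all samples when ``group`` is None.  Requires >= 3 samples;
    pairs with fewer than ``min_shared`` mutually complete samples are
    marked undefined (NaN).
    """
    values = table.group_values(group) if group else table.values
    if values.shape[1] < 3:
        raise ValueError(f"group {group!r} has fewer than 3 samples")
    x = values.to_numpy(dtype=float)
    notna = ~np.isnan(x)
    counts = (notna.astype(np.int32) @ notna.T.astype(np.int32))
    if notna.all():
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.corrcoef(x)
    else:
        r = values.T.corr(min_periods=min_shared).to_numpy()
    r = np.clip(r, -1.0, 1.0)
    r[counts < min_shared] = np.nan
    np.fill_diagonal(r, 1.0)
    idx = values.index
    return CorrelationMatrix(
        r=pd.DataFrame(r, index=idx, columns=idx),
        n_shared=pd.DataFrame(counts, index=idx, columns=idx),
        min_shared=min_shared,
        group=group,
    )


def build_network(
    corr: CorrelationMatrix,
    tau: float,
    group: str | None = None,
    gene_set: str | None = None,
) -> GeneNetwork:
    """Threshold the correlation matrix into a coexpression graph.

    An edge joins genes i, j iff |r_ij| >= tau (undefined pairs never
    qualify); the sign of r is kept as an edge attribute.  Genes left
    with no edge are dropped from the node set.
    """
    if not 0.0 < tau <= 1.0:
        raise ValueError("tau must be in (0, 1]")
    arr = corr.r.to_numpy()
    genes = corr.gene_ids
    iu, ju = np.triu_indices(len(genes), k=1)
    vals = arr[iu, ju]
    keep = np.isfinite(vals) & (np.abs(vals) >= tau)
    g = nx.Graph()
    for i, j, rv in zip(iu[keep], ju[keep], vals[keep]):
        g.add_edge(genes[i], genes[j], r=float(rv), sign=1 if rv >= 0 else -1)
    return GeneNetwork(
        graph=g,
        threshold=float(tau),
        group=group if group is not None else corr.group,
        gene_set=gene_set,
    )


def _giant_fraction(g: nx.Graph) -> float:
    if g.number_of_nodes() == 0:
        return 0.0
    giant = max((len(c) for c in nx.connected_components(g)), default=0)
    return giant / g.number_of_nodes()


def _partition_ari(labels_a: dict, labels_b: dict) -> float:
    shared = sorted(set(labels_a) & set(labels_b))
    if len(shared) < 2:
        return 0.0
    return float(
        adjusted_rand_score(
            [labels_a[n] for n in shared], [labels_b[n] for n in shared]
        )
    )


def select_threshold(
    corr: CorrelationMatrix,
    grid,
    stability_delta: float = 0.005,
    min_giant_fraction: float = 1.0,
    ari_min: float = 0.8,
    seed: int = 0,
) -> float:
    """Pick the largest threshold that keeps the network whole and its
    community structure stable.

    A grid value tau qualifies when (a) the giant component holds at
    least ``min_giant_fraction`` of the non-isolated nodes and (b) the
    Louvain partitions at tau - delta and tau + delta agree with the
    partition at tau (ARI >= ``ari_min``, restricted to shared nodes).
    Raises with a per-tau diagnostics table when nothing qualifies.
    """
    from .community import louvain  # local import: community depends on network

    grid = sorted(float(t) for t in grid)
    diagnostics = []
    chosen: float | None = None
    for tau in grid:
        net = build_network(corr, tau)
        row = {
            "tau": tau,
            "n_nodes": net.n_nodes,
            "n_edges": net.n_edges,
            "giant_fraction": _giant_fraction(net.graph),
            "ari_minus": np.nan,
            "ari_plus": np.nan,
        }
        if net.n_edges == 0 or row["giant_fraction"] < min_giant_fraction:
            diagnostics.append(row)
            continue
        part = louvain(net, seed=seed).labels
        aris = []
        for sign, key in ((-1, "ari_minus"), (+1, "ari_plus")):
            t2 = tau + sign * stability_delta
            if not 0.0 < t2 <= 1.0:
                row[key] = 1.0
                aris.append(1.0)
                continue
            net2 = build_network(corr, t2)
            if net2.n_edges == 0:
                row[key] = 0.0
                aris.append(0.0)
                continue
            part2 = louvain(net2, seed=seed).labels
            row[key] = _partition_ari(part, part2)
            aris.append(row[key])
        if min(aris) >= ari_min:
            chosen = tau
        diagnostics.append(row)
    if chosen is None:
        table = pd.DataFrame(diagnostics).to_string(index=False)
        raise ValueError(
            "no grid threshold satisfies the giant-component and "
            f"stability criteria; diagnostics:\n{table}"
        )
    return chosen


def connectivity(net: GeneNetwork | nx.Graph) -> float:
    """Average connectivity k = 2L/N (0 for an edgeless graph)."""
    g = net.graph if isinstance(net, GeneNetwork) else net
    n = g.number_of_nodes()
    if n == 0 or g.number_of_edges() == 0:
        return 0.0
    return 2.0 * g.number_of_edges() / n


# ---------------------------------------------------------------------------
# Discrete power-law (scale-free) degree-distribution fit
# ---------------------------------------------------------------------------


@dataclass
class PowerLawFit:
    """Discrete power-law fit of a degree sequence.

    ``alpha`` is the ML exponent for the tail x >= xmin, ``ks_distance``
    the Kolmogorov-Smirnov distance of that tail, ``p_value`` the
    optional semiparametric bootstrap goodness-of-fit probability
    (large p = power law not rejected).  ``degenerate`` flags sequences
    (e.g. constant degrees) on which the fit is meaningless.
    """

    alpha: float
    xmin: int
    ks_distance: float
    n_tail: int
    p_value: float | None = None
    bootstrap_reps: int = 0
    degenerate: bool = False


def _zeta(alpha: float, xmin: int) -> float:
    return float(special.zeta(alpha, xmin))


def _fit_alpha(tail: np.ndarray, xmin: int) -> float:
    """Exact discrete MLE: maximise -n*ln zeta(a, xmin) - a*sum(ln x)."""
    slog = float(np.log(tail).sum())
    n = len(tail)

    def nll(a: float) -> float:
        return n * np.log(_zeta(a, xmin)) + a * slog

    res = optimize.minimize_scalar(nll, bounds=(1.01, 10.0), method="bounded")
    return float(res.x)


def _ks_distance(tail: np.ndarray, alpha: float, xmin: int) -> float:
    zx = _zeta(alpha, xmin)
    xs = np.unique(tail)
    # theoretical P(X <= x) = 1 - zeta(alpha, x+1)/zeta(alpha, xmin)
    cdf = 1.0 - special.zeta(alpha, xs + 1.0) / zx
    ecdf = np.searchsorted(np.sort(tail), xs, side="right") / len(tail)
    return float(np.max(np.abs(ecdf - cdf)))


def fit_discrete_powerlaw(
    degrees, xmin: int | None = None, min_tail: int = 10
) -> PowerLawFit:
    """Fit P(x) ~ x^-alpha to integer data, scanning xmin by K-S distance.

    When ``xmin`` is given only the exponent is fitted; otherwise every
    observed value is tried as xmin (keeping at least ``min_tail`` tail
    points) and the one with the smallest K-S distance wins.
    """
    x = np.asarray(list(degrees), dtype=int)
    x = x[x >= 1]
    if len(x) < min_tail or len(np.unique(x)) < 2:
        xm = int(x.min()) if len(x) else 1
        return PowerLawFit(
            alpha=np.nan, xmin=xm, ks_distance=1.0, n_tail=len(x), degenerate=True
        )
    candidates = [int(xmin)] if xmin is not None else [
        int(v) for v in np.unique(x)[:-1]
    ]
    best: PowerLawFit | None = None
    for xm in candidates:
        tail = x[x >= xm]
        if len(tail) < min_tail or len(np.unique(tail)) < 2:
            continue
        alpha = _fit_alpha(tail, xm)
        d = _ks_distance(tail, alpha, xm)
        if best is None or d < best.ks_distance:
            best = PowerLawFit(alpha=alpha, xmin=xm, ks_distance=d, n_tail=len(tail))
    if best is None:
        return PowerLawFit(
            alpha=np.nan, xmin=int(x.min()), ks_distance=1.0,
            n_tail=len(x), degenerate=True,
        )
    return best


def sample_discrete_powerlaw(
    alpha: float, xmin: int, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw integers from the discrete power law p(x) ~ x^-alpha, x >= xmin.

    Inverse-CDF over an explicit support table (extended with the
    continuous approximation in the far tail, which at the sizes used
    here is hit with negligible probability)."""
    cap = 100_000
    support = np.arange(xmin, cap + 1)
    pmf = support.astype(float) ** (-alpha) / _zeta(alpha, xmin)
    cdf = np.cumsum(pmf)
    u = rng.random(size)
    out = support[np.minimum(np.searchsorted(cdf, u), len(support) - 1)]
    overflow = u > cdf[-1]
    if overflow.any():
        # continuous tail approximation, rounded
        ut = (1.0 - u[overflow])
        out = out.astype(float)
        out[overflow] = np.floor((xmin - 0.5) * ut ** (-1.0 / (alpha - 1.0)) + 0.5)
        out = out.astype(int)
    return out


def scalefree_test(
    net: GeneNetwork | nx.Graph,
    bootstrap_reps: int = 0,
    seed: int = 0,
) -> PowerLawFit:
    """Power-law fit of the network's degree distribution.

    With ``bootstrap_reps`` > 0, runs the semiparametric bootstrap:
    synthetic datasets mix the empirical below-xmin body with power-law
    tail draws from the fitted model; p is the fraction whose refitted
    K-S distance exceeds the observed one (p >= 0.1 conventionally
    means the power law is plausible).
    """
    g = net.graph if isinstance(net, GeneNetwork) else net
    degrees = np.array([d for _, d in g.degree()], dtype=int)
    fit = fit_discrete_powerlaw(degrees)
    if fit.degenerate or bootstrap_reps <= 0:
        return fit
    rng = np.random.default_rng(seed)
    x = degrees[degrees >= 1]
    body = x[x < fit.xmin]
    p_tail = fit.n_tail / len(x)
    exceed = 0
    for _ in range(bootstrap_reps):
        take_tail = rng.random(len(x)) < p_tail
        n_tail = int(take_tail.sum())
        synth = np.concatenate(
            [
                sample_discrete_powerlaw(fit.alpha, fit.xmin, n_tail, rng),
                rng.choice(body, size=len(x) - n_tail, replace=True)
                if len(body)
                else np.empty(0, dtype=int),
            ]
        )
        refit = fit_discrete_powerlaw(synth)
        if refit.degenerate or refit.ks_distance > fit.ks_distance:
            exceed += 1
    return PowerLawFit(
        alpha=fit.alpha,
        xmin=fit.xmin,
        ks_distance=fit.ks_distance,
        n_tail=fit.n_tail,
        p_value=exceed / bootstrap_reps,
        bootstrap_reps=bootstrap_reps,
    )
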