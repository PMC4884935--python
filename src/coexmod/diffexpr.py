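"""Two-class differential expression: SAM for genes, t-test for miRNAs.

SAM (significance analysis of microarrays, Tusher-style two-class
unpaired) scores each gene with a moderated statistic

    d_i = (mean2_i - mean1_i) / (s_i + s0)

where s_i is the pooled standard error and s0 an exchangeability
constant chosen from the percentiles of s_i to minimise the coefficient
of variation of d's scatter across s-quantile windows.  The null
distribution of order statistics is estimated by permuting group
labels; genes whose ordered d deviates from the permutation-averaged
expected order by more than ``delta`` are called, and the FDR is the
median permutation false-call count over the observed call count.

miRNAs use the plain equal-variance unpaired t-test at p < alpha, with
no multiple-testing correction (raw p < 0.05 is the classic-microarray
convention).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import ExpressionTable

__all__ = ["SamResult", "TTestResult", "sam_two_class", "ttest_unpaired"]

_S0_PERCENTILES = np.arange(0, 101, 5)
_N_WINDOWS = 100


def _group_masks(table: ExpressionTable) -> tuple[np.ndarray, np.ndarray]:
    g1, g2 = table.group_names
    cols = np.asarray([table.groups[s] for s in table.values.columns])
    return cols == g1, cols == g2


def _d_components(
    x: np.ndarray, in_g1: np.ndarray, in_g2: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene numerator r = mean2 - mean1 and pooled scatter s."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        x1, x2 = x[:, in_g1], x[:, in_g2]
        n1 = np.sum(~np.isnan(x1), axis=1).astype(float)
        n2 = np.sum(~np.isnan(x2), axis=1).astype(float)
        m1, m2 = np.nanmean(x1, axis=1), np.nanmean(x2, axis=1)
        ss1 = np.nansum((x1 - m1[:, None]) ** 2, axis=1)
        ss2 = np.nansum((x2 - m2[:, None]) ** 2, axis=1)
    dof = n1 + n2 - 2
    with np.errstate(invalid="ignore", divide="ignore"):
        s = np.sqrt((1.0 / n1 + 1.0 / n2) * (ss1 + ss2) / dof)
    return m2 - m1, s


def _tune_s0(r: np.ndarray, s: np.ndarray) -> float:
    """Percentile search for the exchangeability constant s0.

    For each candidate (a percentile of s) compute d = r/(s + cand),
    bin genes into s-quantile windows, and measure the coefficient of
    variation of the windows' median absolute deviations; the candidate
    minimising that CV makes d's scatter independent of s.
    """
    order = np.argsort(s, kind="stable")
    s_sorted, r_sorted = s[order], r[order]
    edges = np.linspace(0, len(s), _N_WINDOWS + 1).astype(int)
    windows = [
        slice(a, b) for a, b in zip(edges[:-1], edges[1:]) if b > a
    ]
    candidates = np.percentile(s, _S0_PERCENTILES)
    best_s0, best_cv = float(candidates[0]), np.inf
    for cand in candidates:
        with np.errstate(invalid="ignore", divide="ignore"):
            d = r_sorted / (s_sorted + cand)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mads = np.array(
                [
                    np.nanmedian(np.abs(d[w] - np.nanmedian(d[w]))) / 0.64
                    for w in windows
                ]
            )
        mads = mads[np.isfinite(mads)]
        if len(mads) < 2 or np.mean(mads) == 0:
            continue
        cv = np.std(mads) / np.mean(mads)
        if cv < best_cv:
            best_cv, best_s0 = cv, float(cand)
    return best_s0


def _permutation_masks(
    n_samples: int, n1: int, n_permutations: int, rng: np.random.Generator
) -> np.ndarray:
    """Boolean masks (B x n_samples) of group-1 membership per permutation;
    exhaustive when fewer distinct assignments exist than requested."""
    total = comb(n_samples, n1)
    if total <= n_permutations:
        masks = np.zeros((total, n_samples), dtype=bool)
        for b, idx in enumerate(itertools.combinations(range(n_samples), n1)):
            masks[b, list(idx)] = True
        return masks
    masks = np.zeros((n_permutations, n_samples), dtype=bool)
    for b in range(n_permutations):
        masks[b, rng.choice(n_samples, size=n1, replace=False)] = True
    return masks


@dataclass
class SamResult:
    """SAM output: per-gene table plus the tuned globals.

    ``per_gene`` columns: d, s, fold_change (linear group2/group1),
    called (bool), direction ("up"/"down" in group 2, or "").
    ``expected_order`` holds the permutation-averaged sorted d used for
    calling; ``fdr`` is the median-false-call estimate at ``delta``.
    """

    per_gene: pd.DataFrame
    s0: float
    delta: float
    fdr: float
    n_permutations: int
    seed: int
    expected_order: np.ndarray
    _perm_d: np.ndarray | None = None

    @property
    def called(self) -> list[str]:
        return list(self.per_gene.index[self.per_gene["called"]])

    def delta_table(self, deltas) -> pd.DataFrame:
        """Calls and estimated FDR across a grid of delta cutoffs."""
        rows = []
        d = self.per_gene["d"].to_numpy()
        for delta in deltas:
            called, fdr, _, _ = _call_at_delta(
                d, self.expected_order, self._perm_d, float(delta)
            )
            rows.append((float(delta), int(called.sum()), fdr))
        return pd.DataFrame(rows, columns=["delta", "n_called", "fdr"])


def _call_at_delta(
    d: np.ndarray,
    expected: np.ndarray,
    perm_d: np.ndarray | None,
    delta: float,
) -> tuple[np.ndarray, float, float, float]:
    """Tusher calling rule: thresholds where the observed order
    statistics first exceed the expected order by delta."""
    order = np.argsort(d, kind="stable")
    d_sorted = d[order]
    diff = d_sorted - expected

    cut_up = np.inf
    above = np.nonzero((diff >= delta) & (d_sorted > 0))[0]
    if len(above):
        cut_up = d_sorted[above[0]]
    cut_low = -np.inf
    below = np.nonzero((diff <= -delta) & (d_sorted < 0))[0]
    if len(below):
        cut_low = d_sorted[below[-1]]

    called = (d >= cut_up) | (d <= cut_low)
    n_called = int(called.sum())
    fdr = 0.0
    if n_called and perm_d is not None:
        false_per_perm = np.sum((perm_d >= cut_up) | (perm_d <= cut_low), axis=1)
        fdr = min(1.0, float(np.median(false_per_perm)) / n_called)
    return called, fdr, cut_up, cut_low


def sam_two_class(
    table: ExpressionTable,
    n_permutations: int = 1000,
    delta: float = 1.0,
    seed: int = 0,
) -> SamResult:
    """Two-class unpaired SAM with permutation-estimated FDR.

    Genes with fewer than two complete samples in a group are skipped
    with a warning.  Deterministic for a given seed (permutation draws
    are seeded); invariant to gene order and within-group sample order.
    """
    if len(table.group_names) != 2:
        raise ValueError("SAM requires exactly two groups")
    x = table.values.to_numpy(dtype=float)
    in_g1, in_g2 = _group_masks(table)

    n_ok1 = np.sum(~np.isnan(x[:, in_g1]), axis=1)
    n_ok2 = np.sum(~np.isnan(x[:, in_g2]), axis=1)
    usable = (n_ok1 >= 2) & (n_ok2 >= 2)
    if not usable.all():
        warnings.warn(
            f"skipping {int((~usable).sum())} genes with <2 complete "
            "samples in a group",
            stacklevel=2,
        )
    genes = table.values.index[usable]
    x = x[usable]

    r, s = _d_components(x, in_g1, in_g2)
    s0 = _tune_s0(r, s)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = r / (s + s0)
    d = np.nan_to_num(d, nan=0.0)

    # permutation null: sorted d* averaged across label reshuffles
    rng = np.random.default_rng(seed)
    n_samples = x.shape[1]
    n1 = int(in_g1.sum())
    masks = _permutation_masks(n_samples, n1, n_permutations, rng)
    perm_d = np.empty((len(masks), len(d)))
    for b, mask1 in enumerate(masks):
        rb, sb = _d_components(x, mask1, ~mask1)
        with np.errstate(invalid="ignore", divide="ignore"):
            perm_d[b] = np.nan_to_num(rb / (sb + s0), nan=0.0)
    expected = np.sort(perm_d, axis=1).mean(axis=0)

    called, fdr, _, _ = _call_at_delta(d, expected, perm_d, delta)
    direction = np.where(called, np.where(d > 0, "up", "down"), "")
    per_gene = pd.DataFrame(
        {
            "d": d,
            "s": s,
            "fold_change": 2.0 ** r,
            "called": called,
            "direction": direction,
        },
        index=genes,
    )
    return SamResult(
        per_gene=per_gene,
        s0=s0,
        delta=delta,
        fdr=fdr,
        n_permutations=len(masks),
        seed=seed,
        expected_order=expected,
        _perm_d=perm_d,
    )


@dataclass
class TTestResult:
    """Equal-variance t-test output: per-miRNA t, p, direction, call."""

    per_gene: pd.DataFrame
    alpha: float

    @property
    def called(self) -> list[str]:
        return list(self.per_gene.index[self.per_gene["call"]])


def ttest_unpaired(table: ExpressionTable, alpha: float = 0.05) -> TTestResult:
    """Pooled-variance unpaired t-test per row, call at p < alpha.

    t is computed group1-vs-group2 (positive t = higher in group 1);
    ``direction`` reports up/down in group 2 from the mean difference.
    Degenerate rows with zero pooled variance and equal means get
    t = 0, p = 1.
    """
    if len(table.group_names) != 2:
        raise ValueError("t-test requires exactly two groups")
    x = table.values.to_numpy(dtype=float)
    in_g1, in_g2 = _group_masks(table)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        x1, x2 = x[:, in_g1], x[:, in_g2]
        n1 = np.sum(~np.isnan(x1), axis=1).astype(float)
        n2 = np.sum(~np.isnan(x2), axis=1).astype(float)
        m1, m2 = np.nanmean(x1, axis=1), np.nanmean(x2, axis=1)
        ss1 = np.nansum((x1 - m1[:, None]) ** 2, axis=1)
        ss2 = np.nansum((x2 - m2[:, None]) ** 2, axis=1)
    dof = n1 + n2 - 2
    with np.errstate(invalid="ignore", divide="ignore"):
        sp2 = (ss1 + ss2) / dof
        se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        t = (m1 - m2) / se
    diff = m2 - m1
    zero_se = ~np.isfinite(t)
    t = np.where(zero_se & (diff == 0), 0.0, t)
    with np.errstate(invalid="ignore"):
        p = 2.0 * stats.t.sf(np.abs(t), dof)
    p = np.where(zero_se & (diff == 0), 1.0, p)
    p = np.where(np.isfinite(p), p, np.nextafter(0, 1))
    p = np.clip(p, np.nextafter(0, 1), 1.0)
    call = p < alpha
    per_gene = pd.DataFrame(
        {
            "t": t,
            "p": p,
            "direction": np.where(diff > 0, "up", np.where(diff < 0, "down", "")),
            "call": call,
        },
        index=table.values.index,
    )
    return TTestResult(per_gene=per_gene, alpha=alpha)
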