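"""Expression-table container and pre-network filtering.

Raw two-colour-free single-channel microarray intensities arrive as a
genes x samples table plus a per-spot quality-flag table.  The cleaning
cascade is:

1. ``flags_to_na``    - spots with >= 2 quality flags become NA.
2. ``log2_transform`` - positive intensities to log2; non-positive to NA.
3. ``collapse_to_genes`` - replicate probes averaged per gene symbol.
4. ``filter_by_group_na`` - drop genes with too many NAs in either group
   (3 for mRNA arrays, 2 for miRNA arrays).

All downstream stages (differential expression, coexpression networks)
consume the :class:`ExpressionTable` this module produces.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionTable",
    "GROUP_NA_LIMITS",
    "flags_to_na",
    "log2_transform",
    "collapse_to_genes",
    "filter_by_group_na",
]

#: Default per-group NA limits: a gene is dropped when its NA count in
#: EITHER group reaches the modality's limit.
GROUP_NA_LIMITS = {"mRNA": 3, "miRNA": 2}


@dataclass
class ExpressionTable:
    """Genes x samples expression matrix with group labels.

    Parameters
    ----------
    values
        DataFrame indexed by gene id (unique strings), one column per
        sample; missing measurements are ``NaN`` (written as literal
        ``NA`` on disk).
    groups
        Series mapping every sample (column of *values*) to one of two
        group labels, e.g. ``CT`` / ``DS``.
    modality
        ``"mRNA"`` or ``"miRNA"``; binds the default NA limit.
    """

    values: pd.DataFrame
    groups: pd.Series
    modality: str = "mRNA"

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("gene ids must be unique")
        self.groups = pd.Series(self.groups)
        missing = [s for s in self.values.columns if s not in self.groups.index]
        if missing:
            raise ValueError(f"samples without a group label: {missing[:5]}")
        self.groups = self.groups.loc[self.values.columns]

    # -- convenience accessors -------------------------------------------

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def group_names(self) -> list[str]:
        seen: list[str] = []
        for g in self.groups:
            if g not in seen:
                seen.append(g)
        return seen

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.groups[s] == group]

    def group_values(self, group: str) -> pd.DataFrame:
        return self.values[self.samples_in(group)]

    def na_counts_per_group(self) -> pd.DataFrame:
        """NA count per gene (rows) per group (columns)."""
        out = {}
        for g in self.group_names:
            out[g] = self.group_values(g).isna().sum(axis=1)
        return pd.DataFrame(out)

    def with_values(self, values: pd.DataFrame) -> "ExpressionTable":
        return replace(self, values=values, groups=self.groups.copy())


def _check_two_groups(table: ExpressionTable) -> None:
    if len(table.group_names) != 2:
        raise ValueError(
            f"expected exactly two sample groups, found {table.group_names}"
        )


def flags_to_na(
    raw: pd.DataFrame, flags: pd.DataFrame, min_flags: int = 2
) -> pd.DataFrame:
    """Mask low-quality spots: entries with ``min_flags`` or more quality
    flags (low intensity, saturation, controls, ...) become NA.

    *raw* and *flags* must share shape, index and columns; flag counts
    are non-negative integers.
    """
    if raw.shape != flags.shape:
        raise ValueError(f"shape mismatch: values {raw.shape} vs flags {flags.shape}")
    if not raw.index.equals(flags.index) or not raw.columns.equals(flags.columns):
        raise ValueError("flag table index/columns do not match the value table")
    if (flags.to_numpy() < 0).any():
        raise ValueError("flag counts must be non-negative")
    return raw.mask(flags >= min_flags)


def log2_transform(raw: pd.DataFrame) -> pd.DataFrame:
    """log2 of positive intensities; non-positive raw values become NA
    (with a warning), since they carry no usable signal."""
    arr = raw.to_numpy(dtype=float)
    bad = np.isfinite(arr) & (arr <= 0)
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} non-positive intensities set to NA before log2",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(bad, np.nan, np.log2(np.where(bad, np.nan, arr)))
    return pd.DataFrame(out, index=raw.index, columns=raw.columns)


def collapse_to_genes(
    table: ExpressionTable, probe_to_gene: pd.Series | dict
) -> ExpressionTable:
    """Collapse probe-level rows to one row per gene symbol.

    Replicate probes are averaged with an NA-ignoring mean; probes with
    no mapping entry are dropped.  Output genes are ordered by first
    appearance of their probes.
    """
    mapping = pd.Series(probe_to_gene)
    keep = [p for p in table.values.index if p in mapping.index]
    sub = table.values.loc[keep]
    symbols = mapping.loc[keep]
    order = list(dict.fromkeys(symbols))
    collapsed = sub.groupby(symbols.to_numpy(), sort=False).mean()
    collapsed = collapsed.loc[order]
    collapsed.index.name = table.values.index.name
    return table.with_values(collapsed)


def filter_by_group_na(
    table: ExpressionTable, max_na: int | None = None
) -> ExpressionTable:
    """Drop genes with ``max_na`` or more NAs in either group.

    ``max_na`` defaults by modality: 3 for mRNA, 2 for miRNA.  Retained
    rows keep their order and values (mask-only semantics), which makes
    the filter idempotent.
    """
    _check_two_groups(table)
    if max_na is None:
        max_na = GROUP_NA_LIMITS[table.modality]
    if max_na < 1:
        raise ValueError("max_na must be >= 1")
    counts = table.na_counts_per_group()
    keep = (counts < max_na).all(axis=1)
    return table.with_values(table.values.loc[keep])
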