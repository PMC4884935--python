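"""Synthetic two-group expression data with planted structure.

Emulates the experimental design the pipeline targets: a two-group (control vs
case) single-channel microarray experiment with

* blockwise-correlated gene modules (one latent factor per module,
  loadings uniform in [0.7, 1]),
* one-sided differential expression (planted DE genes are up-regulated
  in group 2 only),
* background genes that are i.i.d. noise (a calibrated null for
  correlation-threshold selection),
* a companion miRNA table with planted down/up-regulated miRNAs and a
  small "abundant" subset whose linear-scale mean far exceeds the
  global average in both groups,
* an evidence-tagged miRNA-target table covering planted module genes.

Full-scale defaults: ~13,000 genes x (10+10) samples
for mRNA and 641 miRNAs x (8+8) samples with 47 down- / 6 up-regulated
and 6 abundant miRNAs.  Every generator is a pure function of its
config (same seed, same bytes).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import ExpressionTable

__all__ = [
    "SyntheticConfig",
    "PlantedTruth",
    "generate_expression",
    "generate_mirna",
    "generate_target_table",
]


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic two-group experiment.

    ``factor_strength`` is the fraction of a module gene's variance
    explained by its module factor (at loading 1), so it directly
    drives within-module Pearson correlation; it must lie in [0, 1).
    ``de_effect`` and ``noise_sd`` are in log2-intensity units.
    """

    n_genes: int = 13000
    n_samples_per_group: int = 10
    n_modules: int = 0
    module_sizes: tuple[int, ...] = ()
    factor_strength: float = 0.9
    de_fraction: float = 0.04
    de_effect: float = 1.5
    noise_sd: float = 0.4
    na_rate: float = 0.0
    seed: int = 0
    group_names: tuple[str, str] = ("CT", "DS")
    baseline_range: tuple[float, float] = (6.0, 12.0)
    # miRNA-specific planting (used by generate_mirna only)
    mirna_n_down: int = 47
    mirna_n_up: int = 6
    mirna_n_abundant: int = 6
    abundance_factor: float = 50.0
    mirna_baseline: float = 7.0

    def __post_init__(self) -> None:
        self.module_sizes = tuple(int(s) for s in self.module_sizes)
        if self.n_modules == 0 and self.module_sizes:
            self.n_modules = len(self.module_sizes)
        if self.n_modules != len(self.module_sizes):
            raise ValueError("n_modules must equal len(module_sizes)")
        if sum(self.module_sizes) > self.n_genes:
            raise ValueError(
                f"module_sizes sum to {sum(self.module_sizes)} "
                f"> n_genes = {self.n_genes}"
            )
        if not 0.0 <= self.factor_strength < 1.0:
            raise ValueError("factor_strength must be in [0, 1)")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValueError("de_fraction must be in [0, 1]")
        if not 0.0 <= self.na_rate < 1.0:
            raise ValueError("na_rate must be in [0, 1)")

    @classmethod
    def mirna_default(cls, **kw) -> "SyntheticConfig":
        """Study-scale miRNA defaults: 641 miRNAs, 8+8 samples, planted
        47 down / 6 up at 2 log2 units, 6 abundant at 50x baseline."""
        kw.setdefault("n_genes", 641)
        kw.setdefault("n_samples_per_group", 8)
        kw.setdefault("de_effect", 2.0)
        kw.setdefault("noise_sd", 0.3)
        return cls(**kw)


@dataclass
class PlantedTruth:
    """Ground truth planted by the generators.

    ``module_of`` maps each module gene to its module label; genes not in
    the mapping are background noise.  Direction strings are relative to
    group 2 ("up" = higher in group 2).
    """

    module_of: dict[str, str] = field(default_factory=dict)
    de_genes: dict[str, str] = field(default_factory=dict)
    de_mirnas: dict[str, str] = field(default_factory=dict)
    abundant_mirnas: set[str] = field(default_factory=set)
    target_pairs: list[tuple[str, str, str]] = field(default_factory=list)

    def merged_with(self, other: "PlantedTruth") -> "PlantedTruth":
        """Combine gene-side and miRNA-side truths into one object."""
        return PlantedTruth(
            module_of={**self.module_of, **other.module_of},
            de_genes={**self.de_genes, **other.de_genes},
            de_mirnas={**self.de_mirnas, **other.de_mirnas},
            abundant_mirnas=self.abundant_mirnas | other.abundant_mirnas,
            target_pairs=self.target_pairs + other.target_pairs,
        )


def _orthogonal_factors(
    rng: np.random.Generator, n_modules: int, n_per_group: int
) -> np.ndarray:
    """Per-module latent factors, orthogonalised within each group.

    Factors are Gaussian but made mutually orthogonal over each group's
    samples (QR), so planted modules are distinct blocks even at small
    sample sizes, where independently drawn factors can correlate
    strongly by chance.  Requires n_modules <= samples per group.
    """
    if n_modules > n_per_group:
        raise ValueError("n_modules cannot exceed samples per group")
    cols = []
    for _ in range(2):  # the two groups
        raw = rng.normal(size=(n_per_group, n_modules))
        q, _ = np.linalg.qr(raw)
        cols.append((q * np.sqrt(n_per_group)).T)
    return np.concatenate(cols, axis=1)


def _plant_modules(
    values: np.ndarray,
    genes: list[str],
    config: SyntheticConfig,
    rng: np.random.Generator,
    truth: "PlantedTruth",
) -> None:
    """Add the per-module latent-factor signal in place (rows 0..sum(sizes))."""
    if not config.module_sizes or config.factor_strength == 0:
        for m, size in enumerate(config.module_sizes):
            start = sum(config.module_sizes[:m])
            for g in genes[start : start + size]:
                truth.module_of[g] = f"M{m + 1}"
        return
    sigma_f = config.noise_sd * np.sqrt(
        config.factor_strength / (1.0 - config.factor_strength)
    )
    factors = _orthogonal_factors(
        rng, len(config.module_sizes), config.n_samples_per_group
    )
    row = 0
    for m, size in enumerate(config.module_sizes):
        loadings = rng.uniform(0.7, 1.0, size=size)
        values[row : row + size] += (
            sigma_f * loadings[:, None] * factors[m][None, :]
        )
        for g in genes[row : row + size]:
            truth.module_of[g] = f"M{m + 1}"
        row += size


def _sample_sheet(config: SyntheticConfig, prefix: str = "S") -> pd.Series:
    n = config.n_samples_per_group
    g1, g2 = config.group_names
    samples = [f"{prefix}{i + 1:02d}" for i in range(2 * n)]
    return pd.Series([g1] * n + [g2] * n, index=samples, name="group")


def generate_expression(
    config: SyntheticConfig,
) -> tuple[ExpressionTable, PlantedTruth]:
    """Generate a two-group mRNA table with planted modules and DE genes.

    Module gene i in module m, sample s:

        x_is = baseline_i + loading_i * sigma_f * f_ms + eps_is

    with f a unit-variance factor shared per (module, sample) —
    orthogonalised across modules within each group — eps ~
    N(0, noise_sd^2) and sigma_f chosen so that factor_strength is the
    factor's variance share at loading 1.  DE genes get +de_effect
    added in group 2 only; ``na_rate`` of all entries are masked
    completely at random.
    """
    rng = np.random.default_rng(config.seed)
    n_genes, n = config.n_genes, config.n_samples_per_group
    n_samples = 2 * n
    genes = [f"G{i + 1:05d}" for i in range(n_genes)]
    groups = _sample_sheet(config)

    baseline = rng.uniform(*config.baseline_range, size=n_genes)
    values = baseline[:, None] + rng.normal(
        0.0, config.noise_sd, size=(n_genes, n_samples)
    )

    truth = PlantedTruth()
    _plant_modules(values, genes, config, rng, truth)

    n_de = int(round(config.de_fraction * n_genes))
    if n_de:
        de_idx = rng.choice(n_genes, size=n_de, replace=False)
        values[de_idx, n:] += config.de_effect
        truth.de_genes = {genes[i]: "up" for i in sorted(de_idx)}

    if config.na_rate > 0:
        mask = rng.random(size=values.shape) < config.na_rate
        values = np.where(mask, np.nan, values)

    df = pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=groups.index)
    return ExpressionTable(df, groups, modality="mRNA"), truth


def generate_mirna(
    config: SyntheticConfig,
) -> tuple[ExpressionTable, PlantedTruth]:
    """Generate a two-group miRNA table with planted DE and abundant sets.

    miRNAs share a flat log2 baseline (so the global linear mean is a
    meaningful abundance reference); ``mirna_n_abundant`` of them sit at
    ``abundance_factor`` times that baseline in both groups, and
    ``mirna_n_down`` / ``mirna_n_up`` receive -/+ ``de_effect`` in
    group 2.  The DE, abundant and module sets are drawn disjointly
    where possible.
    """
    rng = np.random.default_rng(config.seed + 1)
    n_mir, n = config.n_genes, config.n_samples_per_group
    n_samples = 2 * n
    if config.mirna_n_down + config.mirna_n_up + config.mirna_n_abundant > n_mir:
        raise ValueError("planted miRNA sets exceed n_genes")
    mirnas = [f"miR-{i + 1:04d}" for i in range(n_mir)]
    groups = _sample_sheet(config, prefix="M")

    values = config.mirna_baseline + rng.normal(
        0.0, config.noise_sd, size=(n_mir, n_samples)
    )

    truth = PlantedTruth()
    _plant_modules(values, mirnas, config, rng, truth)
    order = rng.permutation(n_mir)
    n_ab = config.mirna_n_abundant
    ab_idx = order[:n_ab]
    down_idx = order[n_ab : n_ab + config.mirna_n_down]
    up_idx = order[
        n_ab + config.mirna_n_down : n_ab + config.mirna_n_down + config.mirna_n_up
    ]

    # Abundant rows are pinned per group so their realized linear mean is
    # exactly abundance_factor x the non-abundant baseline — the planted
    # "abundant" status then holds in both groups by construction, not
    # merely in expectation.
    if len(ab_idx):
        other = np.ones(n_mir, dtype=bool)
        other[ab_idx] = False
        for sl in (slice(0, n), slice(n, n_samples)):
            linear = 2.0 ** values[:, sl]
            baseline = linear[other].mean(axis=1).mean()
            row_means = linear[ab_idx].mean(axis=1)
            shift = np.log2(config.abundance_factor * baseline / row_means)
            values[ab_idx, sl] += shift[:, None]
    values[down_idx, n:] -= config.de_effect
    values[up_idx, n:] += config.de_effect

    truth.abundant_mirnas = {mirnas[i] for i in ab_idx}
    truth.de_mirnas = {mirnas[i]: "down" for i in sorted(down_idx)}
    truth.de_mirnas.update({mirnas[i]: "up" for i in sorted(up_idx)})

    if config.na_rate > 0:
        mask = rng.random(size=values.shape) < config.na_rate
        values = np.where(mask, np.nan, values)

    df = pd.DataFrame(values, index=pd.Index(mirnas, name="mirna"), columns=groups.index)
    return ExpressionTable(df, groups, modality="miRNA"), truth


def generate_target_table(
    truth: PlantedTruth,
    coverage: float,
    seed: int,
    validated_fraction: float = 0.3,
) -> pd.DataFrame:
    """Build an evidence-tagged miRNA-target table from planted truth.

    Links every planted DE miRNA to a random ``coverage`` fraction of
    the planted module genes (all miRNA x gene pairs over the selected
    genes, so coverage=1 yields the complete bipartite pair set).  Each
    pair is tagged ``validated`` with probability ``validated_fraction``
    else ``predicted``.  The emitted pairs are also recorded in
    ``truth.target_pairs``.
    """
    if not 0.0 <= coverage <= 1.0:
        raise ValueError("coverage must be in [0, 1]")
    rng = np.random.default_rng(seed)
    mirnas = sorted(truth.de_mirnas)
    module_genes = sorted(truth.module_of)
    n_sel = int(round(coverage * len(module_genes)))
    rows: list[tuple[str, str, str, str]] = []
    if n_sel and mirnas:
        sel = sorted(rng.choice(module_genes, size=n_sel, replace=False))
        for mir in mirnas:
            for gene in sel:
                evidence = (
                    "validated" if rng.random() < validated_fraction else "predicted"
                )
                rows.append((mir, gene, evidence, "synthetic"))
    table = pd.DataFrame(rows, columns=["mirna", "gene", "evidence", "source"])
    truth.target_pairs = [(m, g, e) for m, g, e, _ in rows]
    return table
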