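"""End-to-end pipeline: expression tables -> networks -> communities -> miRNA.

Stage order follows the analysis design: differential expression (SAM
for genes, t-test for miRNAs) feeds the DE networks; all valid genes
feed the CO networks; each network gets hierarchy categorisation,
Louvain communities, a mixing matrix and a coarse-grained community
graph; finally DE miRNAs are integrated through the target table.

Every stage is a pure function of (inputs, config); all randomness
derives from the single top-level seed recorded in the run manifest,
so identical configs reproduce identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as cio
from .community import (
    community_subnetworks,
    louvain,
    mixing_matrix,
    coarse_grain,
)
from .diffexpr import sam_two_class, ttest_unpaired
from .hierarchy import HierarchyConfig, classify_nodes, high_hierarchy_set
from .mirna import flag_abundant, integrate_co_hh, integrate_de
from .network import build_network, pearson_matrix, scalefree_test, select_threshold
from .preprocess import ExpressionTable, filter_by_group_na
from .synthetic import (
    SyntheticConfig,
    generate_expression,
    generate_mirna,
    generate_target_table,
)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs, serialisable to YAML.

    With ``expression_path`` unset the run simulates its inputs from
    the ``synthetic_*`` blocks.  Threshold grids are (start, stop,
    step) inclusive ranges.  ``min_giant_fraction`` defaults to 0.3:
    block-structured (modular) data cannot place every node in one
    component at informative thresholds, so the selector only requires
    a substantial giant component; raise it toward 1.0 for data
    expected to be globally connected.
    """

    outdir: str = "coexmod_run"
    seed: int = 0
    # inputs (paths win over simulation)
    expression_path: str | None = None
    samples_path: str | None = None
    mirna_path: str | None = None
    mirna_samples_path: str | None = None
    targets_path: str | None = None
    synthetic_mrna: dict = field(default_factory=dict)
    synthetic_mirna: dict = field(default_factory=dict)
    target_coverage: float = 0.3
    # stage toggles
    run_de: bool = True
    run_co: bool = True
    run_mirna: bool = True
    # differential expression
    sam_permutations: int = 200
    sam_delta: float = 1.0
    ttest_alpha: float = 0.05
    # networks
    de_grid: tuple[float, float, float] = (0.80, 0.97, 0.01)
    co_grid: tuple[float, float, float] = (0.80, 0.99, 0.01)
    stability_delta: float = 0.005
    min_giant_fraction: float = 0.3
    ari_min: float = 0.8
    # hierarchy
    hub_quantile: float = 0.90
    highhub_k1_quantile: float = 0.90
    vip_max_quantile: float = 0.50
    vip_neighbor_hub_fraction: float = 1.0
    # communities
    louvain_restarts: int = 10
    subnetwork_min_size: int = 100
    # miRNA
    abundance_factor: float = 30.0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, payload: dict) -> "PipelineConfig":
        cfg = cls(**payload)
        cfg.de_grid = tuple(cfg.de_grid)
        cfg.co_grid = tuple(cfg.co_grid)
        return cfg

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def hierarchy_config(self) -> HierarchyConfig:
        return HierarchyConfig(
            hub_quantile=self.hub_quantile,
            highhub_k1_quantile=self.highhub_k1_quantile,
            vip_max_quantile=self.vip_max_quantile,
            vip_neighbor_hub_fraction=self.vip_neighbor_hub_fraction,
        )


def _grid(spec: tuple[float, float, float]) -> np.ndarray:
    start, stop, step = spec
    return np.round(np.arange(start, stop + step / 2, step), 10)


def _load_inputs(config: PipelineConfig):
    if config.expression_path:
        table = cio.read_expression(
            config.expression_path, config.samples_path, modality="mRNA"
        )
        truth = None
    else:
        syn = SyntheticConfig(**{"seed": config.seed, **config.synthetic_mrna})
        table, truth = generate_expression(syn)
    mirna_table = mirna_truth = None
    if config.run_mirna:
        if config.mirna_path:
            mirna_table = cio.read_expression(
                config.mirna_path, config.mirna_samples_path, modality="miRNA"
            )
        else:
            syn_mi = SyntheticConfig.mirna_default(
                **{"seed": config.seed, **config.synthetic_mirna}
            )
            mirna_table, mirna_truth = generate_mirna(syn_mi)
    targets = None
    if config.run_mirna:
        if config.targets_path:
            targets = cio.read_target_table(config.targets_path)
        elif truth is not None and mirna_truth is not None:
            targets = generate_target_table(
                truth.merged_with(mirna_truth),
                coverage=config.target_coverage,
                seed=config.seed + 7,
            )
    return table, truth, mirna_table, mirna_truth, targets


def _analyse_network(
    table: ExpressionTable,
    genes,
    group: str,
    gene_set: str,
    grid,
    config: PipelineConfig,
    outdir: Path,
) -> dict:
    """One network's full analysis: threshold, hierarchy, communities."""
    sub = table.with_values(table.values.loc[[g for g in genes]])
    corr = pearson_matrix(sub, group=group)
    tau = select_threshold(
        corr,
        grid,
        stability_delta=config.stability_delta,
        min_giant_fraction=config.min_giant_fraction,
        ari_min=config.ari_min,
        seed=config.seed,
    )
    net = build_network(corr, tau, group=group, gene_set=gene_set)
    fit = scalefree_test(net)
    hier = classify_nodes(net, config.hierarchy_config())
    hh = high_hierarchy_set(hier)
    part = louvain(net, seed=config.seed, n_restarts=config.louvain_restarts)
    mm = mixing_matrix(net, part)
    cgcs = coarse_grain(net, part, hh_genes=hh if gene_set == "CO" else None)

    tag = f"{group}-{gene_set}"
    cio.write_edgelist(net, outdir / f"{tag}_edges.tsv")
    cio.write_graphml(net, outdir / f"{tag}_network.graphml")
    cio.write_hierarchy(hier, outdir / f"{tag}_hierarchy.tsv")
    cio.write_membership(part.labels, outdir / f"{tag}_membership.tsv")
    mm.e.to_csv(outdir / f"{tag}_mixing_e.tsv", sep="\t")
    mm.w.to_csv(outdir / f"{tag}_mixing_w.tsv", sep="\t")
    cio.write_graphml(cgcs, outdir / f"{tag}_cgcs.graphml")

    summary = {
        **net.summary(),
        "modularity": part.q,
        "n_communities": part.n_communities,
        "n_hh_genes": len(hh),
        "powerlaw_alpha": fit.alpha,
        "powerlaw_xmin": fit.xmin,
        "powerlaw_ks": fit.ks_distance,
    }
    if gene_set == "CO":
        subnets = community_subnetworks(
            table, part, tau, min_size=config.subnetwork_min_size, group=group
        )
        subnets.to_csv(outdir / f"{tag}_subnetworks.tsv", sep="\t", index=False)
        summary["n_subnetworks"] = len(subnets)
    cio.write_json(summary, outdir / f"{tag}_summary.json")
    return {
        "summary": summary,
        "network": net,
        "hierarchy": hier,
        "hh": hh,
        "partition": part,
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every enabled stage and return the report bundle.

    The bundle maps stage names to their in-memory results; all files
    land under ``config.outdir`` together with a ``manifest.json``
    recording seed, config hash and per-stage element counts.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table, truth, mirna_table, mirna_truth, targets = _load_inputs(config)

    counts: dict = {"genes_in": int(table.values.shape[0])}
    table = filter_by_group_na(table)
    counts["genes_after_na_filter"] = int(table.values.shape[0])
    groups = table.group_names

    bundle: dict = {"table": table, "truth": truth, "results": {}}
    de_genes: list = []
    de_mirnas: dict = {}
    abundant: set = set()

    if config.run_de:
        sam = sam_two_class(
            table,
            n_permutations=config.sam_permutations,
            delta=config.sam_delta,
            seed=config.seed,
        )
        sam.per_gene.to_csv(outdir / "sam_results.tsv", sep="\t")
        de_genes = sam.called
        counts["de_genes"] = len(de_genes)
        bundle["sam"] = sam

    if config.run_mirna and mirna_table is not None:
        mirna_table = filter_by_group_na(mirna_table)
        tt = ttest_unpaired(mirna_table, alpha=config.ttest_alpha)
        tt.per_gene.to_csv(outdir / "mirna_ttest.tsv", sep="\t")
        de_mirnas = dict(
            tt.per_gene.loc[tt.per_gene["call"], "direction"]
        )
        abundant = flag_abundant(mirna_table, factor=config.abundance_factor)
        counts["de_mirnas"] = len(de_mirnas)
        counts["abundant_mirnas"] = len(abundant)
        bundle["ttest"] = tt
        bundle["abundant"] = abundant

    for group in groups:
        if config.run_de and len(de_genes) >= 3:
            res = _analyse_network(
                table, de_genes, group, "DE", _grid(config.de_grid), config, outdir
            )
            bundle["results"][f"{group}-DE"] = res
            if targets is not None and de_mirnas:
                graph = integrate_de(
                    res["network"], de_genes, res["hierarchy"], de_mirnas,
                    targets, abundant=abundant,
                )
                cio.write_graphml(graph, outdir / f"{group}-DE_integrative.graphml")
                res["summary"]["n_integrative_nodes"] = graph.number_of_nodes()
        if config.run_co:
            res = _analyse_network(
                table, list(table.values.index), group, "CO",
                _grid(config.co_grid), config, outdir,
            )
            bundle["results"][f"{group}-CO"] = res
            if targets is not None and de_mirnas:
                graph = integrate_co_hh(
                    res["network"], res["hierarchy"], de_mirnas, targets,
                    abundant=abundant,
                )
                cio.write_graphml(graph, outdir / f"{group}-CO_integrative.graphml")
                res["summary"]["n_integrative_nodes"] = graph.number_of_nodes()

    manifest = {
        "seed": config.seed,
        "config_hash": config.content_hash(),
        "config": config.to_dict(),
        "counts": counts,
        "networks": {
            key: res["summary"] for key, res in bundle["results"].items()
        },
    }
    cio.write_json(manifest, outdir / "manifest.json")
    bundle["manifest"] = manifest
    return bundle
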