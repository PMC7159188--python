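"""End-to-end orchestration of the co-expression / integration analysis.

Runs, in order: correlation -> soft-threshold selection -> adjacency -> TOM
-> module detection -> eigengenes/kME -> module-trait statistics -> module
selection -> hub and HGS selection -> differential expression -> abundant/DE
miRNA selection -> TF candidate filtering -> integrative network assembly.
Each stage is an importable function of its own module; this driver only
wires them together under one :class:`~thymonet.types.RunConfig`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from . import integrate, mirna as mirna_mod, network, select, trait
from .types import (
    ExpressionMatrix,
    InteractionTable,
    RunConfig,
    SampleMetadata,
    trait_designs,
)

log = logging.getLogger("thymonet.pipeline")


@dataclass
class NetworkResult:
    soft_threshold: network.SoftThresholdReport
    adjacency: network.Adjacency
    tom: network.TOMatrix
    modules: network.ModuleAssignment
    eigengenes: network.EigengeneMatrix
    kme: pd.DataFrame


@dataclass
class PipelineResult:
    network: NetworkResult
    module_trait: trait.ModuleTraitResult
    significant_pairs: list[tuple[str, str, float, float]]
    connectivity: pd.DataFrame
    hubs: pd.DataFrame
    hgs: pd.DataFrame
    de: pd.DataFrame
    mirna_cutoffs: "mirna_mod.AbundanceCutoffs | None" = None
    abundant_by_group: dict[str, list[str]] = field(default_factory=dict)
    abundant_union: list[str] = field(default_factory=list)
    mirna_de: pd.DataFrame | None = None
    tf_candidates: list[str] = field(default_factory=list)
    integrative: nx.Graph | None = None
    edge_report: pd.DataFrame | None = None


def run_network(mrna: ExpressionMatrix, config: RunConfig) -> NetworkResult:
    corr = network.correlation_matrix(mrna)
    sft = network.pick_soft_threshold(
        corr, grid=config.soft_power_grid, r2_cutoff=config.r2_cutoff,
        network_type=config.network_type)
    adj = network.adjacency_from_correlation(
        corr, sft.chosen_beta, config.network_type)
    tom = network.topological_overlap(adj)
    modules = network.cluster_and_cut(
        tom, min_module_size=config.min_module_size,
        deep_split=config.deep_split, expr=mrna)
    me = network.module_eigengenes(mrna, modules)
    kme = network.module_membership(mrna, me)
    return NetworkResult(sft, adj, tom, modules, me, kme)


def run_pipeline(
    mrna: ExpressionMatrix,
    meta: SampleMetadata,
    config: RunConfig | None = None,
    mirna_expr: ExpressionMatrix | None = None,
    tf_expr: ExpressionMatrix | None = None,
    tf_target: InteractionTable | None = None,
    mirna_tf: InteractionTable | None = None,
    mirna_cutoffs: "mirna_mod.AbundanceCutoffs | None" = None,
) -> PipelineResult:
    """Run the full analysis; miRNA/TF/integration stages are optional."""
    config = config or RunConfig()
    net = run_network(mrna, config)
    traits = trait_designs(meta)
    mt = trait.module_trait_analysis(mrna, net.eigengenes, net.modules, traits)
    sig = trait.select_significant_modules(mt, alpha=config.alpha_module)
    sig_modules = sorted({m for m, *_ in sig})
    sig_pairs = [(m, t) for m, t, _, _ in sig]

    conn = select.intramodular_connectivity(net.adjacency, net.modules)
    hubs = select.select_hubs(conn, sig_modules,
                              hub_quantile=config.hub_quantile)
    hgs = select.select_hgs(mt.gs, net.kme, net.modules, sig_pairs,
                            alpha=config.alpha_module, cap=config.hgs_cap)
    sig_genes = [g for c in sig_modules for g in net.modules.genes_in(c)]
    de = (select.de_results(mrna.subset_features(sig_genes), meta,
                            alpha=config.alpha_de)
          if sig_genes else pd.DataFrame())

    result = PipelineResult(
        network=net, module_trait=mt, significant_pairs=sig,
        connectivity=conn, hubs=hubs, hgs=hgs, de=de)

    if mirna_expr is not None:
        mirna_meta_samples = [s for s in mirna_expr.sample_ids
                              if s in meta.sample_ids]
        if len(mirna_meta_samples) < mirna_expr.n_samples:
            raise ValueError("miRNA samples missing from metadata")
        cutoffs = mirna_cutoffs or mirna_mod.knee_cutoffs_per_group(
            mirna_expr, meta)
        by_group, union = mirna_mod.abundant_mirnas(mirna_expr, meta, cutoffs)
        result.mirna_cutoffs = cutoffs
        result.abundant_by_group = by_group
        result.abundant_union = union
        result.mirna_de = mirna_mod.mirna_anova(mirna_expr, meta,
                                                alpha=config.alpha_mirna)

    hub_hgs_genes = sorted(set(hubs.index) | set(hgs["gene"])
                           if len(hgs) else set(hubs.index))
    if tf_expr is not None and tf_target is not None:
        result.tf_candidates = integrate.filter_tf_candidates(
            tf_target, hub_hgs_genes, set(tf_expr.feature_ids))

    if (mirna_expr is not None and tf_expr is not None
            and hub_hgs_genes and result.abundant_union):
        genes = mrna.subset_features(hub_hgs_genes)
        mir = mirna_expr.subset_features(result.abundant_union)
        tfs = (tf_expr.subset_features(result.tf_candidates)
               if result.tf_candidates else tf_expr.subset_features([]))
        corrs = {
            "gene_gene": integrate._pairwise_r(genes, genes, "gene-gene"),
            "gene_mirna": integrate._pairwise_r(genes, mir, "gene-miRNA"),
            "gene_tf": (integrate._pairwise_r(genes, tfs, "gene-TF")
                        if tfs.n_features else
                        pd.DataFrame(index=genes.feature_ids, columns=[])),
        }
        hub_set, hgs_set = set(hubs.index), (set(hgs["gene"])
                                             if len(hgs) else set())
        roles = {}
        node_modules = {}
        for g in hub_hgs_genes:
            roles[g] = ("hub+hgs" if g in hub_set and g in hgs_set
                        else "hub" if g in hub_set else "hgs")
            node_modules[g] = str(net.modules.labels.get(g, ""))
        for mi in result.abundant_union:
            roles[mi] = "mirna"
        for tf in result.tf_candidates:
            roles[tf] = "tf"
        result.integrative = integrate.build_integrative_network(
            corrs, roles, node_modules, config, validated_mirna_tf=mirna_tf)
        result.edge_report = integrate.round_report_correlations(
            result.integrative)
    return result
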