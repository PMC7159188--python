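"""TF-miRNA-mRNA integrative co-expression network and offline enrichment.

Edges are typed, signed Pearson correlations over shared samples, admitted by
the sign-constrained thresholds of the integrative analysis: gene-gene edges
need |r| >= 0.70 (both signs kept), gene-miRNA edges need r <= -0.50
(negative only; a positive correlation never becomes an edge), gene-TF edges
need |r| >= 0.50.  Curated miRNA-TF interactions annotate TF nodes/edges as
"validated" but never create co-expression edges by themselves.  The Enrichr
surrogate is a one-sided hypergeometric over-representation test with
Benjamini-Hochberg adjustment over user-supplied GMT collections.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import (
    ExpressionMatrix,
    GeneSetCollection,
    InteractionTable,
    RunConfig,
)

log = logging.getLogger("thymonet.integrate")


def _pairwise_r(a: ExpressionMatrix, b: ExpressionMatrix,
                what: str) -> pd.DataFrame:
    """Pearson r for every (row of a) × (row of b) pair over shared samples."""
    shared = [s for s in a.sample_ids if s in set(b.sample_ids)]
    if not shared:
        raise ValueError(f"{what}: empty sample intersection")
    if len(shared) < 3:
        raise ValueError(f"{what}: fewer than 3 shared samples")
    x = a.subset_samples(shared).values
    y = b.subset_samples(shared).values
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError(f"{what}: missing values; filter first")

    def _z(v):
        sd = v.std(axis=1, keepdims=True)
        if (sd == 0).any():
            raise ValueError(f"{what}: zero-variance profile")
        return (v - v.mean(axis=1, keepdims=True)) / sd

    r = np.clip(_z(x) @ _z(y).T / len(shared), -1, 1)
    log.info("%s: %d x %d correlations over %d shared samples", what,
             r.shape[0], r.shape[1], len(shared))
    return pd.DataFrame(r, index=a.feature_ids, columns=b.feature_ids)


def cross_correlations(genes: ExpressionMatrix, mirnas: ExpressionMatrix,
                       tfs: ExpressionMatrix) -> dict[str, pd.DataFrame]:
    """gene-gene, gene-miRNA and gene-TF correlation tables.

    Gene and TF profiles share the mRNA sample set; gene-miRNA pairs are
    evaluated on the intersection of the mRNA and miRNA sample sets.
    """
    return {
        "gene_gene": _pairwise_r(genes, genes, "gene-gene"),
        "gene_mirna": _pairwise_r(genes, mirnas, "gene-miRNA"),
        "gene_tf": _pairwise_r(genes, tfs, "gene-TF"),
    }


def filter_tf_candidates(tf_edges: InteractionTable, genes: list[str],
                         expressed_tfs: set[str]) -> list[str]:
    """TFs with an interaction edge to >= 1 hub/HGS gene that are also expressed."""
    if tf_edges.kind != "tf_target":
        raise ValueError("expected a tf_target interaction table")
    gene_set = set(genes)
    tfs = sorted({
        src for src, tgt in tf_edges.pairs()
        if tgt in gene_set and src in expressed_tfs
    })
    log.info("TF candidates: %d of %d interacting TFs are expressed",
             len(tfs), tf_edges.edges["source"].nunique())
    return tfs


def build_integrative_network(
    correlations: dict[str, pd.DataFrame],
    node_roles: dict[str, str],
    node_modules: dict[str, str],
    config: RunConfig,
    validated_mirna_tf: InteractionTable | None = None,
) -> nx.Graph:
    """Assemble the typed, thresholded co-expression network.

    ``node_roles`` maps each declared node to hub / hgs / hub+hgs / mirna /
    tf; declared nodes are retained even when isolated.  Gene-gene edges keep
    both signs (|r| >= thr_gene_gene); gene-miRNA edges admit only
    r <= -thr_gene_mirna; gene-TF edges need |r| >= thr_gene_tf.  A gene-TF
    edge is flagged validated when the curated miRNA-TF table links its TF to
    any miRNA node of the network.
    """
    net = nx.Graph()
    for node, role in node_roles.items():
        net.add_node(node, role=role, module=node_modules.get(node, ""))
    validated_pairs = (validated_mirna_tf.pairs()
                       if validated_mirna_tf is not None else set())
    mirna_nodes = {n for n, r in node_roles.items() if r == "mirna"}

    def _validated_tf(tf: str) -> bool:
        return any((mi, tf) in validated_pairs or (tf, mi) in validated_pairs
                   for mi in mirna_nodes)

    def _add(u: str, v: str, r: float, edge_type: str, validated: bool):
        if u == v or u not in net or v not in net:
            return
        net.add_edge(u, v, r=float(r), edge_type=edge_type,
                     sign="+" if r >= 0 else "-", validated=bool(validated))

    gg = correlations["gene_gene"]
    for i, u in enumerate(gg.index):
        for j in range(i + 1, gg.shape[1]):
            r = float(gg.iat[i, j])
            if abs(r) >= config.thr_gene_gene:
                _add(u, gg.columns[j], r, "gene-gene", False)
    gm = correlations["gene_mirna"]
    for u in gm.index:
        for v in gm.columns:
            r = float(gm.loc[u, v])
            if r <= -config.thr_gene_mirna:
                _add(u, v, r, "gene-mirna",
                     (v, u) in validated_pairs or (u, v) in validated_pairs)
    gt = correlations["gene_tf"]
    for u in gt.index:
        for v in gt.columns:
            r = float(gt.loc[u, v])
            if abs(r) >= config.thr_gene_tf:
                _add(u, v, r, "gene-tf", _validated_tf(v))
    log.info("integrative network: %d nodes, %d edges (%s)",
             net.number_of_nodes(), net.number_of_edges(),
             dict(pd.Series([d["edge_type"]
                             for _, _, d in net.edges(data=True)]
                            ).value_counts()) if net.number_of_edges() else {})
    return net


def round_half_away(r: float, decimals: int = 1) -> float:
    """Round half away from zero (so -0.55 reports as -0.6)."""
    scale = 10 ** decimals
    return float(np.copysign(np.floor(abs(r) * scale + 0.5) / scale, r))


def round_report_correlations(net: nx.Graph, decimals: int = 1) -> pd.DataFrame:
    """Reporting view of the edge list with r rounded half away from zero.

    Raw correlations stay untouched on the network object.
    """
    rows = [
        {"source": u, "target": v, "edge_type": d["edge_type"],
         "r": d["r"], "r_reported": round_half_away(d["r"], decimals),
         "sign": d["sign"], "validated": d["validated"]}
        for u, v, d in sorted(net.edges(data=True))
    ]
    return pd.DataFrame(rows, columns=["source", "target", "edge_type", "r",
                                       "r_reported", "sign", "validated"])


def hypergeometric_ora(query: list[str], universe: list[str],
                       sets: GeneSetCollection,
                       adjust: str = "bh") -> pd.DataFrame:
    """One-sided hypergeometric over-representation of query genes per set.

    p = P(overlap >= observed) drawing |query| genes from the universe;
    gene-set members outside the universe are ignored for the test.
    """
    uni = set(universe)
    outside = [g for g in query if g not in uni]
    if outside:
        raise ValueError(f"query gene(s) outside universe: {outside[:5]}")
    q = set(query)
    rows = []
    for name, genes in sets.sets.items():
        members = set(genes) & uni
        overlap = sorted(q & members)
        k = len(overlap)
        p = float(stats.hypergeom.sf(k - 1, len(uni), len(members), len(q)))
        rows.append({"set": name, "set_size": len(members),
                     "overlap": k, "p": min(p, 1.0),
                     "overlap_genes": ",".join(overlap)})
    out = pd.DataFrame(rows).set_index("set")
    if adjust == "bh":
        out["p_adj"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    elif adjust in (None, "none"):
        out["p_adj"] = out["p"]
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")
    return out.sort_values("p")
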