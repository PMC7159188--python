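"""Hub and HGS gene selection plus the differential-expression layer.

Hubs are the most intramodularly connected genes (top kWithin quantile) of
each trait-significant module.  HGS ("high gene significance") genes are the
most trait-correlated members of significant (module, trait) pairs, capped at
a fixed pool size.  The DE layer compares neonate vs oldest groups (Wilcoxon
rank-sum), tests across all five groups (one-way ANOVA with Benjamini-
Hochberg adjustment), and reports a signed fold change from log2 group means.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .network import Adjacency, ModuleAssignment
from .types import GREY, ExpressionMatrix, SampleMetadata

log = logging.getLogger("thymonet.select")


def intramodular_connectivity(adj: Adjacency,
                              modules: ModuleAssignment) -> pd.DataFrame:
    """kTotal, kWithin and kOut per gene; grey genes get kWithin = 0."""
    genes = adj.gene_ids
    labels = modules.labels.reindex(genes)
    if labels.isna().any():
        missing = list(labels.index[labels.isna()])[:5]
        raise ValueError(f"genes without module label: {missing}")
    a = adj.a.copy()
    np.fill_diagonal(a, 0.0)
    k_total = a.sum(axis=1)
    k_within = np.zeros(len(genes))
    lab = labels.to_numpy()
    for color in pd.unique(lab):
        if color == GREY:
            continue
        idx = np.flatnonzero(lab == color)
        k_within[idx] = a[np.ix_(idx, idx)].sum(axis=1)
    return pd.DataFrame(
        {"module": lab, "kTotal": k_total, "kWithin": k_within,
         "kOut": k_total - k_within},
        index=genes,
    )


def select_hubs(conn: pd.DataFrame, significant_modules: list[str],
                hub_quantile: float = 0.05) -> pd.DataFrame:
    """Top-connectivity genes of each significant module.

    Within each module the ceil(hub_quantile * module size) genes with the
    highest kWithin are returned; ties break by kTotal, then gene id.
    """
    if not 0 < hub_quantile < 1:
        raise ValueError("hub_quantile must lie in (0, 1)")
    out = []
    for color in significant_modules:
        block = conn[conn["module"] == color]
        if not len(block):
            continue
        n_hubs = math.ceil(hub_quantile * len(block))
        # descending kWithin, then kTotal, then ascending gene id
        ranked = block.iloc[
            np.lexsort((block.index.to_numpy(),
                        -block["kTotal"].to_numpy(),
                        -block["kWithin"].to_numpy()))
        ]
        out.append(ranked.head(n_hubs))
    if not out:
        return conn.iloc[:0]
    hubs = pd.concat(out)
    log.info("selected %d hub(s) from %d module(s)", len(hubs),
             len(significant_modules))
    return hubs


def select_hgs(gs: dict[str, pd.DataFrame], mm: pd.DataFrame,
               modules: ModuleAssignment,
               significant_pairs: list[tuple[str, str]],
               alpha: float = 0.05, cap: int = 50) -> pd.DataFrame:
    """High-gene-significance genes pooled across significant (module, trait) pairs.

    Candidates are members of a significant pair whose GS p-value for that
    trait is below alpha; candidates rank by |GS| descending and the pool is
    capped at ``cap`` distinct genes (a gene may carry several traits, e.g.
    significant for both the neonate and the oldest group).
    """
    if cap < 1:
        raise ValueError("cap must be >= 1")
    rows = []
    for module, trait in significant_pairs:
        if trait not in gs:
            raise ValueError(f"no GS table for trait {trait!r}")
        table = gs[trait]
        for gene in modules.genes_in(module):
            if gene not in table.index:
                continue
            g, p = float(table.loc[gene, "GS"]), float(table.loc[gene, "p"])
            if p < alpha:
                rows.append({
                    "gene": gene, "module": module, "trait": trait,
                    "GS": g, "p": p, "abs_GS": abs(g),
                    "MM": float(mm.loc[gene, module]) if (
                        gene in mm.index and module in mm.columns) else np.nan,
                    "direction": "hyper" if g > 0 else "hypo",
                })
    if not rows:
        return pd.DataFrame(columns=["gene", "module", "trait", "GS", "p",
                                     "MM", "direction"])
    cand = pd.DataFrame(rows).sort_values(
        by=["abs_GS", "gene", "trait"], ascending=[False, True, True],
        kind="mergesort").reset_index(drop=True)
    chosen_genes: list[str] = []
    keep_idx = []
    for i, row in cand.iterrows():
        if row["gene"] not in chosen_genes:
            if len(chosen_genes) == cap:
                continue
            chosen_genes.append(row["gene"])
        keep_idx.append(i)
    hgs = cand.loc[keep_idx].drop(columns="abs_GS").reset_index(drop=True)
    log.info("selected %d HGS gene(s) (%d gene-trait records)",
             len(chosen_genes), len(hgs))
    return hgs


def _group_values(m: ExpressionMatrix, meta: SampleMetadata,
                  group: str) -> np.ndarray:
    cols = [s for s in meta.samples_in_group(group) if s in m.data.columns]
    if len(cols) < 2:
        raise ValueError(f"group {group!r} has fewer than 2 samples")
    return m.data[cols].to_numpy()


def wilcoxon_de(m: ExpressionMatrix, meta: SampleMetadata,
                group_x: str = "A", group_y: str = "E") -> pd.Series:
    """Two-sided Wilcoxon rank-sum p per gene between two age groups.

    Exact enumeration is used for small tie-free samples (n_x + n_y <= 12),
    the tie-corrected normal approximation otherwise.
    """
    xs = _group_values(m, meta, group_x)
    ys = _group_values(m, meta, group_y)
    n_small = xs.shape[1] + ys.shape[1] <= 12
    ps = np.empty(m.n_features)
    for i in range(m.n_features):
        x, y = xs[i], ys[i]
        has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
        method = "exact" if (n_small and not has_ties) else "asymptotic"
        ps[i] = stats.mannwhitneyu(x, y, alternative="two-sided",
                                   method=method).pvalue
    return pd.Series(np.minimum(ps, 1.0), index=m.feature_ids,
                     name=f"wilcoxon_p_{group_x}_vs_{group_y}")


def anova_de(m: ExpressionMatrix, meta: SampleMetadata,
             adjust: str = "bh") -> pd.DataFrame:
    """One-way fixed-effects ANOVA p per gene across age groups, BH-adjusted."""
    groups = [g for g, s in meta.groups().items()
              if len([c for c in s if c in m.data.columns]) >= 2]
    if len(groups) < 2:
        raise ValueError("ANOVA requires at least 2 groups with >= 2 samples")
    blocks = [_group_values(m, meta, g) for g in groups]
    ps = np.empty(m.n_features)
    for i in range(m.n_features):
        samples = [b[i] for b in blocks]
        if all(np.ptp(s) == 0 for s in samples) and len(
                {s[0] for s in samples}) == 1:
            ps[i] = 1.0  # identical constant groups: F = 0
            continue
        f, p = stats.f_oneway(*samples)
        ps[i] = 1.0 if np.isnan(p) else p
    if adjust == "bh":
        adj = multipletests(ps, method="fdr_bh")[1]
    elif adjust in (None, "none"):
        adj = ps
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")
    return pd.DataFrame({"anova_p": ps, "anova_p_adj": adj},
                        index=m.feature_ids)


def fold_change(m: ExpressionMatrix, meta: SampleMetadata,
                group_x: str = "A", group_y: str = "E") -> pd.Series:
    """Signed fold change from log2 group means.

    delta = mean_log2(X) - mean_log2(Y); FC = 2^delta when delta >= 0, else
    -2^(-delta), so |FC| >= 1 and FC carries the direction of group X.
    """
    mx = np.nanmean(_group_values(m, meta, group_x), axis=1)
    my = np.nanmean(_group_values(m, meta, group_y), axis=1)
    delta = mx - my
    fc = np.where(delta >= 0, 2.0 ** delta, -(2.0 ** (-delta)))
    return pd.Series(fc, index=m.feature_ids,
                     name=f"fold_change_{group_x}_over_{group_y}")


def de_results(m: ExpressionMatrix, meta: SampleMetadata,
               group_x: str = "A", group_y: str = "E",
               alpha: float = 0.05) -> pd.DataFrame:
    """Combined DE table: Wilcoxon p, BH-adjusted ANOVA p, signed FC, direction."""
    wt = wilcoxon_de(m, meta, group_x, group_y)
    an = anova_de(m, meta)
    fc = fold_change(m, meta, group_x, group_y)
    hyper = np.where(wt >= alpha, "none",
                     np.where(fc > 1, group_x, np.where(fc < -1, group_y, "none")))
    return pd.DataFrame({
        "wilcoxon_p": wt, "anova_p_adj": an["anova_p_adj"],
        "fold_change": fc, "hyper_group": hyper,
    })
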