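"""Weighted co-expression network construction.

Pipeline: Pearson correlation of gene profiles -> soft-thresholded adjacency
(|r|^beta unsigned, ((1+r)/2)^beta signed) chosen against a scale-free
topology fit -> topological overlap matrix (TOM) -> average-linkage
hierarchical clustering of 1-TOM -> dynamic branch decomposition into
modules -> module eigengenes (first principal component) and eigengene-based
connectivity (kME).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform

from .types import GREY, MODULE_COLORS, ExpressionMatrix

log = logging.getLogger("thymonet.network")


# ---------------------------------------------------------------------------
# correlation


def correlation_matrix(m: ExpressionMatrix) -> pd.DataFrame:
    """Pearson correlation of every gene pair (pairwise-complete over NAs).

    Requires >= 3 samples overall and >= 3 shared non-missing samples for
    every pair; genes without variance are rejected by name.
    """
    if m.n_samples < 3:
        raise ValueError("correlation requires at least 3 samples")
    vals = m.values
    sd = np.nanstd(vals, axis=1)
    zero = np.flatnonzero(sd == 0)
    if len(zero):
        raise ValueError(
            f"zero-variance feature(s): {[m.feature_ids[i] for i in zero[:5]]}"
        )
    if not m.missing_mask.any():
        z = (vals - vals.mean(axis=1, keepdims=True)) / sd[:, None]
        r = (z @ z.T) / m.n_samples
    else:
        r = m.data.T.corr(min_periods=3).to_numpy()
        if np.isnan(r).any():
            i, j = np.argwhere(np.isnan(r))[0]
            raise ValueError(
                f"fewer than 3 shared samples for pair "
                f"({m.feature_ids[i]!r}, {m.feature_ids[j]!r})"
            )
    np.clip(r, -1.0, 1.0, out=r)
    np.fill_diagonal(r, 1.0)
    return pd.DataFrame(r, index=m.feature_ids, columns=m.feature_ids)


# ---------------------------------------------------------------------------
# adjacency and soft threshold


@dataclass
class Adjacency:
    gene_ids: list[str]
    a: np.ndarray  # symmetric, unit diagonal, values in [0, 1]
    beta: int
    network_type: str

    def __post_init__(self) -> None:
        if self.a.shape != (len(self.gene_ids),) * 2:
            raise ValueError("adjacency shape does not match gene ids")

    def connectivity(self) -> np.ndarray:
        """k_i = sum over j != i of a_ij."""
        return self.a.sum(axis=1) - np.diag(self.a)


def adjacency_from_correlation(r_matrix: pd.DataFrame, beta: int,
                               network_type: str = "unsigned") -> Adjacency:
    if beta < 1 or int(beta) != beta:
        raise ValueError("beta must be an integer >= 1")
    r = r_matrix.to_numpy(dtype=float)
    if network_type == "unsigned":
        a = np.abs(r) ** beta
    elif network_type == "signed":
        a = ((1.0 + r) / 2.0) ** beta
    else:
        raise ValueError(f"unknown network_type {network_type!r}")
    np.fill_diagonal(a, 1.0)
    return Adjacency(list(r_matrix.index), a, int(beta), network_type)


def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """Scale-free topology fit of a connectivity vector.

    Bins k into ``n_bins`` equal-width bins and regresses log10(relative
    frequency) on log10(mean k) over nonempty bins; returns (R^2, slope) of
    that regression.
    """
    k = np.asarray(k, dtype=float)
    if (k < 0).any():
        raise ValueError("connectivity must be nonnegative")
    if len(k) < n_bins:
        raise ValueError("need at least n_bins connectivity values")
    if k.max() == k.min():
        raise ValueError("constant connectivity: single bin, no fit possible")
    counts, edges = np.histogram(k, bins=n_bins, range=(k.min(), k.max()))
    sums, _ = np.histogram(k, bins=edges, weights=k)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    ok = (counts > 0) & (means > 0)
    if ok.sum() < 3:
        raise ValueError("fewer than 3 usable bins for scale-free fit")
    x = np.log10(means[ok])
    y = np.log10(counts[ok] / len(k))
    slope, intercept = np.polyfit(x, y, 1)
    yhat = slope * x + intercept
    ss_res = float(((y - yhat) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return float(r2), float(slope)


@dataclass
class SoftThresholdReport:
    table: pd.DataFrame  # columns: beta, r2, slope, mean_k, median_k
    chosen_beta: int
    reached_cutoff: bool

    def __post_init__(self) -> None:
        if self.chosen_beta not in set(self.table["beta"]):
            raise ValueError("chosen beta not in candidate grid")


def pick_soft_threshold(r_matrix: pd.DataFrame, grid=range(1, 36),
                        r2_cutoff: float = 0.87,
                        network_type: str = "unsigned",
                        n_bins: int = 10) -> SoftThresholdReport:
    """Screen candidate soft powers against the scale-free fit cutoff.

    The chosen beta is the smallest grid value whose fit reaches the cutoff
    with a negative slope; if none qualifies, the beta maximizing R^2 is
    returned with a warning.
    """
    grid = sorted(int(b) for b in grid)
    if not grid:
        raise ValueError("empty soft power grid")
    rows = []
    for beta in grid:
        adj = adjacency_from_correlation(r_matrix, beta, network_type)
        k = adj.connectivity()
        try:
            r2, slope = scale_free_fit(k, n_bins=n_bins)
        except ValueError:
            r2, slope = np.nan, np.nan
        rows.append({"beta": beta, "r2": r2, "slope": slope,
                     "mean_k": float(k.mean()), "median_k": float(np.median(k))})
    table = pd.DataFrame(rows)
    qualifying = table[(table["r2"] >= r2_cutoff) & (table["slope"] < 0)]
    if len(qualifying):
        chosen = int(qualifying["beta"].iloc[0])
        reached = True
    else:
        chosen = int(table.loc[table["r2"].idxmax(), "beta"])
        reached = False
        log.warning(
            "no soft power reached scale-free R2 >= %.2f; falling back to "
            "beta=%d (max R2 = %.3f)", r2_cutoff, chosen,
            float(table["r2"].max()))
    return SoftThresholdReport(table=table, chosen_beta=chosen,
                               reached_cutoff=reached)


# ---------------------------------------------------------------------------
# topological overlap


@dataclass
class TOMatrix:
    gene_ids: list[str]
    tom: np.ndarray  # symmetric in [0, 1], unit diagonal


def topological_overlap(adj: Adjacency) -> TOMatrix:
    """Unsigned topological overlap:

    TOM_ij = (L_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij), where
    L_ij = sum over u != i,j of a_iu * a_uj and k_i = sum over u != i of a_iu.
    """
    a = adj.a.copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    L = a @ a  # includes no diagonal terms since diag(a) = 0
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (L + a) / denom
    np.fill_diagonal(tom, 1.0)
    tom = np.clip(tom, 0.0, 1.0)
    return TOMatrix(adj.gene_ids, tom)


# ---------------------------------------------------------------------------
# module detection


@dataclass
class ModuleAssignment:
    labels: pd.Series  # gene -> colour label; GREY = unassigned
    dendrogram: np.ndarray | None = None  # scipy linkage matrix
    leaf_order: list[str] = field(default_factory=list)

    def module_colors(self) -> list[str]:
        """Non-grey module labels, largest first."""
        sizes = self.labels[self.labels != GREY].value_counts()
        return list(sizes.index)

    def genes_in(self, color: str) -> list[str]:
        return list(self.labels.index[self.labels == color])

    def sizes(self) -> dict[str, int]:
        return self.labels.value_counts().to_dict()


# deep_split -> where the coherence threshold sits inside the detected
# log-similarity gap (0 = just above the incoherent merges, splitting least;
# 4 = just below the coherent merges, splitting most)
_DEEP_SPLIT_POSITION = {0: 0.15, 1: 0.325, 2: 0.5, 3: 0.675, 4: 0.85}
_U_FLOOR = 1e-12


def _coherence_threshold(Z: np.ndarray, min_size: int, deep_split: int) -> float:
    """Merge-similarity threshold separating coherent branches from junctions.

    Soft-thresholding compresses TOM dissimilarities towards 1, so absolute
    dendrogram heights carry little meaning; what separates a module branch
    from a between-module or noise junction is the *scale* of the merge
    similarity u = 1 - height.  Among branches large enough to be modules,
    coherent (within-module) merges and incoherent junctions form two groups
    in log10(u); the threshold is placed inside the boundary gap of a
    two-class minimum-variance split, its exact position set by
    ``deep_split``.
    """
    counts = Z[:, 3]
    u = 1.0 - Z[counts >= min_size, 2]
    # merges at or below the floor (height ~ 1, i.e. no overlap at all) are
    # junctions by definition and must not distort the split search
    x = np.sort(np.log10(u[u > _U_FLOOR]))
    if len(x) < 2:
        return 2.0 * _U_FLOOR  # only junction-scale merges: split everything
    # two-class split minimizing within-class variance (Otsu); robust to the
    # sparse extreme tail of junction similarities, unlike a raw largest gap
    cs, cs2 = np.cumsum(x), np.cumsum(x ** 2)
    n = len(x)
    best, split = np.inf, 1
    for i in range(1, n):
        n0, n1 = i, n - i
        v0 = cs2[i - 1] / n0 - (cs[i - 1] / n0) ** 2
        v1 = (cs2[-1] - cs2[i - 1]) / n1 - ((cs[-1] - cs[i - 1]) / n1) ** 2
        w = (n0 * v0 + n1 * v1) / n
        if w < best:
            best, split = w, i
    lo, hi = x[split - 1], x[split]
    pos = _DEEP_SPLIT_POSITION[deep_split]
    return float(10 ** (lo + (1.0 - pos) * (hi - lo)))


def _decompose(node, min_size: int, u_threshold: float,
               modules: list[list[int]], unassigned: list[int]) -> None:
    if node.count < min_size:
        unassigned.extend(node.pre_order(lambda x: x.id))
        return
    if 1.0 - node.dist < u_threshold:
        # merge similarity at junction scale: the children are distinct
        # objects, never one module
        _decompose(node.left, min_size, u_threshold, modules, unassigned)
        _decompose(node.right, min_size, u_threshold, modules, unassigned)
        return
    # average linkage is monotone, so every merge inside this branch is at
    # least as coherent as this one: take the branch whole
    modules.append(node.pre_order(lambda x: x.id))


def cluster_and_cut(tom: TOMatrix, min_module_size: int = 30,
                    deep_split: int = 2,
                    expr: ExpressionMatrix | None = None,
                    kme_assign_threshold: float = 0.4) -> ModuleAssignment:
    """Average-linkage clustering of 1-TOM with dynamic branch decomposition.

    The dendrogram is decomposed top-down: branches whose merge similarity
    (1 - height) falls below a data-adaptive coherence threshold (see
    :func:`_coherence_threshold`) are split, branches above it become modules
    whole, and branches smaller than ``min_module_size`` dissolve.  Leftover
    genes are assigned to the module whose eigengene they correlate with best
    (|kME| >= ``kme_assign_threshold``) when ``expr`` is provided, else stay
    grey.  Modules are labelled by size rank using the conventional colour
    sequence (largest = turquoise); unassigned genes are grey.
    """
    if min_module_size < 2:
        raise ValueError("min_module_size must be >= 2")
    if deep_split not in _DEEP_SPLIT_POSITION:
        raise ValueError("deep_split must be in 0..4")
    genes = tom.gene_ids
    n = len(genes)
    if min_module_size > n:
        return ModuleAssignment(pd.Series(GREY, index=genes))
    dissim = 1.0 - tom.tom
    np.fill_diagonal(dissim, 0.0)
    Z = sch.linkage(squareform(dissim, checks=False), method="average")
    root = sch.to_tree(Z)
    u_threshold = _coherence_threshold(Z, min_module_size, deep_split)
    module_leaves: list[list[int]] = []
    leftovers: list[int] = []
    _decompose(root, min_module_size, u_threshold, module_leaves, leftovers)

    membership = np.zeros(n, dtype=int)  # 0 = unassigned
    for mi, leaves in enumerate(module_leaves, start=1):
        membership[leaves] = mi

    if expr is not None and leftovers and module_leaves:
        expr = expr.subset_features(genes)
        vals = expr.values
        z = vals - vals.mean(axis=1, keepdims=True)
        sd = z.std(axis=1)
        sd[sd == 0] = np.nan
        z /= sd[:, None]
        n_assigned = 0
        mes = []
        for leaves in module_leaves:
            me = _first_pc(vals[leaves])[0]
            mes.append((me - me.mean()) / me.std())
        for g in leftovers:
            if np.isnan(z[g]).any():
                continue
            kmes = [float(np.mean(z[g] * me)) for me in mes]
            best = int(np.argmax(np.abs(kmes)))
            if abs(kmes[best]) >= kme_assign_threshold:
                membership[g] = best + 1
                n_assigned += 1
        if n_assigned:
            log.info("assigned %d leftover gene(s) to modules by kME",
                     n_assigned)

    # drop modules that fell below the minimum size and rank by final size
    sizes = {mi: int((membership == mi).sum())
             for mi in range(1, len(module_leaves) + 1)}
    ranked = [mi for mi in sorted(sizes, key=lambda mi: (-sizes[mi], mi))
              if sizes[mi] >= min_module_size]
    if len(ranked) > len(MODULE_COLORS):
        raise ValueError("more modules than available colour labels")
    color_of = {mi: MODULE_COLORS[rank] for rank, mi in enumerate(ranked)}
    labels = pd.Series(
        [color_of.get(mi, GREY) for mi in membership], index=genes)
    leaf_order = [genes[i] for i in sch.leaves_list(Z)]
    log.info("detected %d module(s); %d gene(s) grey", len(ranked),
             int((labels == GREY).sum()))
    return ModuleAssignment(labels=labels, dendrogram=Z, leaf_order=leaf_order)


# ---------------------------------------------------------------------------
# eigengenes and module membership


def _first_pc(x: np.ndarray) -> tuple[np.ndarray, float]:
    """First principal component across samples of a genes × samples block.

    Rows are standardized; returns (scores over samples, variance explained).
    """
    z = x - x.mean(axis=1, keepdims=True)
    sd = z.std(axis=1)
    if (sd == 0).any():
        raise ValueError("constant gene in module")
    z /= sd[:, None]
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    me = vt[0]
    var_explained = float(s[0] ** 2 / (s ** 2).sum())
    # sign-align: the eigengene follows the module's mean profile
    mean_profile = z.mean(axis=0)
    if float(me @ mean_profile) < 0:
        me = -me
    return me, var_explained


@dataclass
class EigengeneMatrix:
    me: pd.DataFrame  # modules × samples, each row zero mean / unit variance
    variance_explained: pd.Series


def module_eigengenes(m: ExpressionMatrix,
                      modules: ModuleAssignment) -> EigengeneMatrix:
    """Module eigengene = first principal component of the module's genes."""
    rows = {}
    var = {}
    for color in modules.module_colors():
        genes = modules.genes_in(color)
        block = m.subset_features(genes)
        if block.missing_mask.any():
            raise ValueError(f"module {color!r} contains missing values; "
                             "filter or impute first")
        if len(genes) == 1:
            log.warning("module %r has a single gene; its eigengene is the "
                        "standardized gene profile", color)
            v = block.values[0]
            me = (v - v.mean()) / v.std()
            ve = 1.0
        else:
            me, ve = _first_pc(block.values)
            me = (me - me.mean()) / me.std()
        rows[color] = me
        var[color] = ve
    me_df = pd.DataFrame(rows, index=m.sample_ids).T
    return EigengeneMatrix(me=me_df, variance_explained=pd.Series(var))


def module_membership(m: ExpressionMatrix, me: EigengeneMatrix) -> pd.DataFrame:
    """kME table: Pearson r of every gene with every module eigengene."""
    shared = [s for s in m.sample_ids if s in me.me.columns]
    if len(shared) < 3:
        raise ValueError("fewer than 3 shared samples between expression "
                         "matrix and eigengenes")
    x = m.subset_samples(shared).values
    z = x - x.mean(axis=1, keepdims=True)
    sd = z.std(axis=1)
    if (sd == 0).any():
        bad = [m.feature_ids[i] for i in np.flatnonzero(sd == 0)[:5]]
        raise ValueError(f"zero-variance feature(s): {bad}")
    z /= sd[:, None]
    e = me.me[shared].to_numpy()
    ez = (e - e.mean(axis=1, keepdims=True)) / e.std(axis=1, keepdims=True)
    kme = (z @ ez.T) / len(shared)
    return pd.DataFrame(np.clip(kme, -1, 1), index=m.feature_ids,
                        columns=list(me.me.index))
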