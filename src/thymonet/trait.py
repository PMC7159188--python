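"""Gene- and module-level trait association.

Gene significance (GS) is the Pearson correlation of a gene's profile with a
binary trait indicator, with a two-sided Student-t p-value.  Two module-level
summaries are computed and reported side by side: the correlation of the
module eigengene with the trait (with its t-test p, used as the significance
gate) and the signed mean of member-gene GS values (module significance, MS).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .network import EigengeneMatrix, ModuleAssignment
from .types import GREY, ExpressionMatrix, TraitDesign

log = logging.getLogger("thymonet.trait")


def _corr_pvalue(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p from t = r * sqrt((n-2) / (1-r^2)) with n-2 df."""
    r = np.clip(np.asarray(r, dtype=float), -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r ** 2, 0.0))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    return np.minimum(p, 1.0)


def gene_significance(m: ExpressionMatrix, trait: TraitDesign) -> pd.DataFrame:
    """Per-gene GS and p for one trait; constant genes are excluded."""
    shared = [s for s in m.sample_ids if s in trait.indicator.index]
    if len(shared) < 4:
        raise ValueError("gene significance requires at least 4 samples")
    x = m.subset_samples(shared).values
    ind = trait.indicator[shared].to_numpy(dtype=float)
    if np.unique(ind).size < 2:
        raise ValueError(f"trait {trait.trait_name!r} has a single class over "
                         "the shared samples")
    sd = x.std(axis=1)
    keep = sd > 0
    if not keep.all():
        log.warning("excluding %d constant gene(s) from GS", int((~keep).sum()))
    z = x[keep] - x[keep].mean(axis=1, keepdims=True)
    z /= sd[keep][:, None]
    t = (ind - ind.mean()) / ind.std()
    gs = np.clip((z @ t) / len(shared), -1, 1)
    p = _corr_pvalue(gs, len(shared))
    return pd.DataFrame(
        {"GS": gs, "p": p},
        index=[g for g, k in zip(m.feature_ids, keep) if k],
    )


def module_significance(gs_table: pd.DataFrame,
                        modules: ModuleAssignment) -> pd.Series:
    """MS per module = signed mean of the member genes' GS values."""
    out = {}
    for color in modules.module_colors():
        members = [g for g in modules.genes_in(color) if g in gs_table.index]
        if not members:
            continue
        out[color] = float(gs_table.loc[members, "GS"].mean())
    return pd.Series(out, name="MS")


@dataclass
class ModuleTraitResult:
    """ME-trait correlations/p-values plus per-trait GS tables and MS."""

    me_trait_r: pd.DataFrame  # modules × traits
    me_trait_p: pd.DataFrame  # modules × traits
    ms: pd.DataFrame  # modules × traits (mean member GS)
    gs: dict[str, pd.DataFrame]  # trait -> per-gene GS table

    def __post_init__(self) -> None:
        if ((self.me_trait_r.to_numpy() < -1).any()
                or (self.me_trait_r.to_numpy() > 1).any()):
            raise ValueError("ME-trait correlation outside [-1, 1]")


def eigengene_trait_correlation(me: EigengeneMatrix,
                                traits: list[TraitDesign]) -> tuple[
                                    pd.DataFrame, pd.DataFrame]:
    """Pearson r and Student-t p for every module eigengene × trait pair."""
    r_rows, p_rows = {}, {}
    for trait in traits:
        shared = [s for s in me.me.columns if s in trait.indicator.index]
        if len(shared) < 4:
            raise ValueError(
                f"trait {trait.trait_name!r}: fewer than 4 shared samples")
        ind = trait.indicator[shared].to_numpy(dtype=float)
        t = (ind - ind.mean()) / ind.std()
        e = me.me[shared].to_numpy()
        ez = (e - e.mean(axis=1, keepdims=True)) / e.std(axis=1, keepdims=True)
        r = np.clip((ez @ t) / len(shared), -1, 1)
        r_rows[trait.trait_name] = r
        p_rows[trait.trait_name] = _corr_pvalue(r, len(shared))
    idx = list(me.me.index)
    return (pd.DataFrame(r_rows, index=idx), pd.DataFrame(p_rows, index=idx))


def module_trait_analysis(m: ExpressionMatrix, me: EigengeneMatrix,
                          modules: ModuleAssignment,
                          traits: list[TraitDesign]) -> ModuleTraitResult:
    """Assemble GS, MS and ME-trait statistics for all traits."""
    r_df, p_df = eigengene_trait_correlation(me, traits)
    gs_tables = {}
    ms_cols = {}
    for trait in traits:
        gs = gene_significance(m, trait)
        gs_tables[trait.trait_name] = gs
        ms_cols[trait.trait_name] = module_significance(gs, modules)
    ms = pd.DataFrame(ms_cols).reindex(r_df.index)
    return ModuleTraitResult(me_trait_r=r_df, me_trait_p=p_df, ms=ms,
                             gs=gs_tables)


def select_significant_modules(result: ModuleTraitResult,
                               alpha: float = 0.05) -> list[tuple[str, str, float, float]]:
    """(module, trait, r, p) pairs with ME-trait p strictly below alpha.

    Sorted by ascending p; grey never qualifies (it is not a module).
    """
    hits = []
    for module in result.me_trait_p.index:
        if module == GREY:
            continue
        for trait in result.me_trait_p.columns:
            p = float(result.me_trait_p.loc[module, trait])
            if p < alpha:
                hits.append((module, trait,
                             float(result.me_trait_r.loc[module, trait]), p))
    hits.sort(key=lambda h: h[3])
    return hits
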