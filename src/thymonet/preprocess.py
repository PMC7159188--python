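"""Probe-level filtering and normalization.

Implements the array-preprocessing chain: flag-based masking of unreliable
spots, the group-wise NA exclusion rule (mRNA: a feature is dropped if any
age group contains even one NA for it; miRNA: dropped if any group is more
than 50% NA), log2 conversion with between-sample quantile normalization, and
a deterministic probe-to-gene collapse.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import ExpressionMatrix, SampleMetadata

log = logging.getLogger("thymonet.preprocess")


@dataclass
class ProbeTable:
    """Raw per-probe intensities with per-cell flag counts.

    ``flags`` counts quality flags (low intensity, saturation, control, ...)
    raised for each spot; dialects that report boolean flag columns should be
    summed into this count before construction.
    """

    intensities: pd.DataFrame  # probes × samples
    flags: pd.DataFrame  # same shape, nonnegative integer counts
    probe_to_gene: dict[str, str] | None = None  # may be partial

    def __post_init__(self) -> None:
        if self.intensities.shape != self.flags.shape:
            raise ValueError("intensity and flag tables differ in shape")
        if not self.intensities.index.equals(self.flags.index):
            raise ValueError("intensity and flag tables differ in probe ids")
        if self.intensities.index.has_duplicates:
            dup = self.intensities.index[self.intensities.index.duplicated()][0]
            raise ValueError(f"duplicate probe id {dup!r}")
        if (self.flags.to_numpy() < 0).any():
            raise ValueError("flag counts must be nonnegative")


def apply_flag_filter(probes: ProbeTable, flag_limit: int = 2) -> ExpressionMatrix:
    """Mask cells whose spot carries ``flag_limit`` or more quality flags."""
    if flag_limit < 1:
        raise ValueError("flag_limit must be >= 1")
    masked = probes.intensities.where(probes.flags < flag_limit)
    n_masked = int(masked.isna().sum().sum()
                   - probes.intensities.isna().sum().sum())
    log.info("flag filter (>=%d flags): masked %d cell(s)", flag_limit, n_masked)
    if masked.isna().all().all():
        log.warning("flag filter masked every cell")
    return ExpressionMatrix(masked)


def filter_by_group_na(m: ExpressionMatrix, meta: SampleMetadata,
                       mode: str) -> ExpressionMatrix:
    """Drop features violating the group-wise NA rule.

    mode='mrna': drop a feature if ANY age group has >= 1 NA for it.
    mode='mirna': drop a feature if ANY age group has an NA fraction > 0.5
    (exactly half NA is kept).
    """
    if mode not in ("mrna", "mirna"):
        raise ValueError(f"unknown mode {mode!r}")
    missing = {s for s in m.sample_ids} - set(meta.sample_ids)
    if missing:
        raise ValueError(f"samples absent from metadata: {sorted(missing)}")
    keep = pd.Series(True, index=m.data.index)
    for group, samples in meta.groups().items():
        cols = [s for s in samples if s in m.data.columns]
        if not cols:
            continue
        na_frac = m.data[cols].isna().sum(axis=1) / len(cols)
        if mode == "mrna":
            keep &= na_frac == 0
        else:
            keep &= na_frac <= 0.5
    n_drop = int((~keep).sum())
    log.info("group-NA filter (%s): kept %d, dropped %d of %d features",
             mode, int(keep.sum()), n_drop, m.n_features)
    if not keep.any():
        raise ValueError("no features survive filtering")
    return ExpressionMatrix(m.data.loc[keep])


def _quantile_normalize(df: pd.DataFrame) -> pd.DataFrame:
    """Between-sample quantile normalization (ties share the mean of means).

    Each sample's sorted values are replaced by the across-sample mean of
    sorted values; tied observations within a sample receive the average of
    the reference values their ranks span.
    """
    vals = df.to_numpy(dtype=float)
    if np.isnan(vals).any():
        raise ValueError("quantile normalization requires a complete matrix; "
                         "apply NA filtering first")
    ref = np.sort(vals, axis=0).mean(axis=1)
    out = np.empty_like(vals)
    for j in range(vals.shape[1]):
        ranks = pd.Series(vals[:, j]).rank(method="average").to_numpy() - 1.0
        lo = np.floor(ranks).astype(int)
        hi = np.ceil(ranks).astype(int)
        out[:, j] = 0.5 * (ref[lo] + ref[hi])
    return pd.DataFrame(out, index=df.index, columns=df.columns)


def normalize_log2_quantile(m: ExpressionMatrix, log2: bool = True,
                            quantile: bool = True) -> ExpressionMatrix:
    """Optionally log2-transform, then quantile-normalize between samples."""
    df = m.data
    if log2:
        bad = np.argwhere((df.to_numpy() <= 0) & ~m.missing_mask)
        if len(bad):
            i, j = bad[0]
            raise ValueError(
                "nonpositive value on linear scale at feature "
                f"{df.index[i]!r}, sample {df.columns[j]!r}; cannot log2"
            )
        df = np.log2(df)
    if quantile and df.shape[1] > 1:
        df = _quantile_normalize(df)
    return ExpressionMatrix(df)


def collapse_probes(m: ExpressionMatrix,
                    probe_to_gene: dict[str, str]) -> ExpressionMatrix:
    """Collapse probes to genes keeping the probe with maximal mean expression.

    Unmapped probes are dropped; ties on mean expression break by
    lexicographically smallest probe id.
    """
    if not probe_to_gene:
        raise ValueError("probe_to_gene mapping is empty")
    means = m.data.mean(axis=1)
    best: dict[str, str] = {}
    for probe in m.data.index:
        gene = probe_to_gene.get(probe)
        if gene is None:
            continue
        cur = best.get(gene)
        if (cur is None
                or means[probe] > means[cur]
                or (means[probe] == means[cur] and probe < cur)):
            best[gene] = probe
    if not best:
        raise ValueError("no probe maps to any gene")
    genes = sorted(best)
    out = m.data.loc[[best[g] for g in genes]]
    out.index = genes
    log.info("collapsed %d probes to %d genes (%d unmapped dropped)",
             m.n_features, len(genes),
             sum(1 for p in m.data.index if p not in probe_to_gene))
    return ExpressionMatrix(out)
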