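"""Abundantly and differentially expressed miRNA selection.

Per age group, an abundance cutoff is placed at the knee of the sorted
expression curve (the point of maximum perpendicular distance to the chord
joining its endpoints); a miRNA is abundant in a group when its mean
expression over the group's samples reaches the cutoff.  Cutoffs chosen by
eye on the real arrays (453/433/610/514/685 for groups A-E) can be forced as
manual overrides.  Differential expression across the five groups uses a raw
one-way ANOVA threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .types import ExpressionMatrix, SampleMetadata

log = logging.getLogger("thymonet.mirna")


@dataclass
class AbundanceCutoffs:
    """Per-group abundance cutoffs on linear intensity scale.

    Abundance is judged on linear intensities (the scale on which the
    distributions are plotted and on which visually chosen cutoffs such as
    453/433/610/514/685 are expressed); the expression matrix itself stays
    log2 and is transformed on the fly.
    """

    cutoffs: dict[str, float]  # age group -> linear-scale cutoff
    method: str = "knee"  # or "manual"

    def __post_init__(self) -> None:
        if self.method not in ("knee", "manual"):
            raise ValueError(f"unknown cutoff method {self.method!r}")
        for g, c in self.cutoffs.items():
            if c <= 0:
                raise ValueError(f"cutoff for group {g!r} must be positive")


def knee_index(values: np.ndarray) -> int:
    """Index of the knee on the sorted-descending abundance curve.

    The knee is the point of maximum perpendicular distance to the chord
    joining the first and last points of the curve.
    """
    v = np.sort(np.asarray(values, dtype=float))[::-1]
    if len(v) < 10:
        raise ValueError("knee detection requires at least 10 values")
    if (v < 0).any():
        raise ValueError("knee detection requires nonnegative values")
    if v[0] == v[-1]:
        raise ValueError("no inflection: constant values")
    n = len(v)
    x = np.arange(n, dtype=float)
    # chord from (0, v[0]) to (n-1, v[-1]); distance of each point to it
    dx, dy = n - 1.0, v[-1] - v[0]
    norm = np.hypot(dx, dy)
    dist = np.abs(dy * x - dx * (v - v[0])) / norm
    if dist.max() < 1e-9 * max(abs(v[0]), abs(v[-1]), 1.0):
        log.warning("abundance curve is essentially linear; knee is "
                    "ill-defined")
    return int(np.argmax(dist))


def knee_cutoff(values: np.ndarray) -> float:
    """Abundance cutoff at the knee of the sorted-descending curve.

    The cutoff is placed halfway between the knee point and its predecessor
    on the curve, i.e. just inside the drop that defines the knee, so that
    the feature sitting exactly at the knee falls below the cutoff rather
    than on it.
    """
    v = np.sort(np.asarray(values, dtype=float))[::-1]
    i = knee_index(v)
    return float(v[i] if i == 0 else 0.5 * (v[i - 1] + v[i]))


def knee_cutoffs_per_group(m: ExpressionMatrix,
                           meta: SampleMetadata) -> AbundanceCutoffs:
    """Knee cutoff of each group's expression-value distribution.

    The knee is found on the group's per-miRNA mean linear intensities; on
    linear scale the abundant tier dominates the curvature of the sorted
    curve, so the knee lands at its lower edge rather than inside the
    background tail.
    """
    cuts = {}
    for group, samples in meta.groups().items():
        cols = [s for s in samples if s in m.data.columns]
        if not cols:
            continue
        means = (2.0 ** m.data[cols]).mean(axis=1).dropna().to_numpy()
        cuts[group] = knee_cutoff(means)
    return AbundanceCutoffs(cutoffs=cuts, method="knee")


def abundant_mirnas(m: ExpressionMatrix, meta: SampleMetadata,
                    cutoffs: AbundanceCutoffs) -> tuple[dict[str, list[str]],
                                                        list[str]]:
    """Per-group abundant miRNA sets and their union.

    A miRNA is abundant in a group when its mean linear intensity over the
    group's samples reaches the group's cutoff (inclusive).
    """
    groups_present = {g for g in meta.groups()
                     if any(s in m.data.columns for s in meta.samples_in_group(g))}
    missing = groups_present - set(cutoffs.cutoffs)
    if missing:
        raise ValueError(f"no cutoff for group(s) {sorted(missing)}")
    per_group: dict[str, list[str]] = {}
    union: list[str] = []
    for group in sorted(groups_present):
        cols = [s for s in meta.samples_in_group(group) if s in m.data.columns]
        means = (2.0 ** m.data[cols]).mean(axis=1)
        hits = list(means.index[means >= cutoffs.cutoffs[group]])
        per_group[group] = hits
        for h in hits:
            if h not in union:
                union.append(h)
    log.info("abundant miRNAs: %s; union %d of %d",
             {g: len(v) for g, v in per_group.items()}, len(union),
             m.n_features)
    return per_group, union


def mirna_anova(m: ExpressionMatrix, meta: SampleMetadata,
                alpha: float = 0.01) -> pd.DataFrame:
    """Raw one-way ANOVA across age groups; rows with p < alpha are flagged DE."""
    groups = [g for g, s in meta.groups().items()
              if len([c for c in s if c in m.data.columns]) >= 2]
    if len(groups) < 2:
        raise ValueError("miRNA ANOVA requires at least 2 age groups")
    blocks = [m.data[[c for c in meta.samples_in_group(g)
                      if c in m.data.columns]].to_numpy() for g in groups]
    ps = np.empty(m.n_features)
    for i in range(m.n_features):
        samples = [b[i] for b in blocks]
        if all(np.ptp(s) == 0 for s in samples) and len(
                {s[0] for s in samples}) == 1:
            ps[i] = 1.0
            continue
        _, p = stats.f_oneway(*samples)
        ps[i] = 1.0 if np.isnan(p) else p
    out = pd.DataFrame({"anova_p": ps, "de": ps < alpha}, index=m.feature_ids)
    log.info("miRNA ANOVA: %d of %d DE at p < %g", int(out["de"].sum()),
             len(out), alpha)
    return out
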