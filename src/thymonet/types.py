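"""Core domain containers shared by every pipeline stage.

All expression data travel as :class:`ExpressionMatrix`, a thin validated
wrapper around a features × samples :class:`pandas.DataFrame` in which ``NaN``
encodes a missing measurement (an Agilent spot flagged away, a probe absent
from a sample).  Values are log2-scale throughout the pipeline unless a
preprocessing step is explicitly asked to transform them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

AGE_GROUPS = ("A", "B", "C", "D", "E")
GENDERS = ("F", "M")

#: Ordered module colour vocabulary (largest module first), matching the
#: conventional co-expression labelling where the biggest module is turquoise
#: and unassigned genes are grey.
MODULE_COLORS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
    "paleturquoise", "violet", "darkolivegreen", "darkmagenta",
    "sienna", "yellowgreen", "skyblue3", "plum", "orangered", "mediumpurple",
)
GREY = "grey"


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise ValueError(f"duplicate {what} id: {x!r}")
        seen.add(x)


@dataclass
class ExpressionMatrix:
    """Log2 expression values, features × samples, with NaN as missing."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            self.data = pd.DataFrame(self.data)
        self.data = self.data.astype(float)
        _check_unique(list(self.data.index), "feature")
        _check_unique(list(self.data.columns), "sample")
        vals = self.data.to_numpy()
        if np.isinf(vals).any():
            i, j = np.argwhere(np.isinf(vals))[0]
            raise ValueError(
                "non-finite expression value at "
                f"feature {self.data.index[i]!r}, sample {self.data.columns[j]!r}"
            )

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def missing_mask(self) -> np.ndarray:
        return self.data.isna().to_numpy()

    @property
    def n_features(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset_features(self, features: Iterable[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[list(features)])

    def subset_samples(self, samples: Iterable[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data[list(samples)])


@dataclass
class SampleMetadata:
    """Per-sample age group (A-E), gender (F/M) and optional age in months."""

    table: pd.DataFrame  # index: sample_id; columns: age_group, gender[, age_months]

    def __post_init__(self) -> None:
        t = self.table
        _check_unique(list(t.index), "sample")
        for col in ("age_group", "gender"):
            if col not in t.columns:
                raise ValueError(f"sample metadata lacks required column {col!r}")
        bad = t.loc[~t["age_group"].isin(AGE_GROUPS)]
        if len(bad):
            raise ValueError(
                "unknown age_group value(s) "
                f"{sorted(bad['age_group'].unique())} in rows {list(bad.index)}; "
                f"expected one of {AGE_GROUPS}"
            )
        bad = t.loc[~t["gender"].isin(GENDERS)]
        if len(bad):
            raise ValueError(
                f"unknown gender value(s) {sorted(bad['gender'].unique())} "
                f"in rows {list(bad.index)}; expected one of {GENDERS}"
            )
        if "age_months" in t.columns and (t["age_months"].dropna() < 0).any():
            raise ValueError("age_months must be nonnegative")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def age_group(self, sample_id: str) -> str:
        return str(self.table.loc[sample_id, "age_group"])

    def samples_in_group(self, group: str) -> list[str]:
        return list(self.table.index[self.table["age_group"] == group])

    def groups(self) -> dict[str, list[str]]:
        return {g: self.samples_in_group(g) for g in AGE_GROUPS
                if (self.table["age_group"] == g).any()}


@dataclass
class TraitDesign:
    """A binary per-sample indicator for one trait (an age group or gender)."""

    trait_name: str
    indicator: pd.Series  # index: sample_id, values in {0, 1}

    def __post_init__(self) -> None:
        vals = set(self.indicator.unique())
        if not vals <= {0, 1, 0.0, 1.0}:
            raise ValueError(f"trait {self.trait_name!r} indicator is not binary")
        if len(vals) < 2:
            raise ValueError(
                f"trait {self.trait_name!r} indicator contains a single class"
            )


def trait_designs(meta: SampleMetadata) -> list[TraitDesign]:
    """One-vs-rest indicators for each age group present, plus gender (M=1)."""
    designs = []
    t = meta.table
    gender = pd.Series((t["gender"] == "M").astype(float), index=t.index)
    if gender.nunique() == 2:
        designs.append(TraitDesign("gender", gender))
    for g in AGE_GROUPS:
        ind = pd.Series((t["age_group"] == g).astype(float), index=t.index)
        if ind.nunique() == 2:
            designs.append(TraitDesign(g, ind))
    return designs


INTERACTION_KINDS = ("tf_target", "mirna_tf", "mirna_target")


@dataclass
class InteractionTable:
    """Curated interaction edges (TF-target, miRNA-TF or miRNA-target)."""

    kind: str
    edges: pd.DataFrame  # columns: source, target, evidence

    def __post_init__(self) -> None:
        if self.kind not in INTERACTION_KINDS:
            raise ValueError(f"unknown interaction kind {self.kind!r}")
        for col in ("source", "target"):
            if col not in self.edges.columns:
                raise ValueError(f"interaction table lacks column {col!r}")
        if "evidence" not in self.edges.columns:
            self.edges = self.edges.assign(evidence="")
        dup = self.edges.duplicated(subset=["source", "target"])
        if dup.any():
            raise ValueError(
                f"duplicate interaction pair(s): "
                f"{self.edges.loc[dup, ['source', 'target']].to_records(index=False)[:3]}"
            )

    def pairs(self) -> set[tuple[str, str]]:
        return set(zip(self.edges["source"], self.edges["target"]))

    def __len__(self) -> int:
        return len(self.edges)


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT-style), used for offline over-representation."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if len(genes) < 1:
                raise ValueError(f"gene set {name!r} is empty")


@dataclass
class RunConfig:
    """All tunable pipeline parameters with their literature-derived defaults.

    Defaults follow the thymic study setup: soft powers 1-35 screened against
    a scale-free fit cutoff of R2 = 0.87, unsigned network, module detection
    with minimum size 30 at deep-split 2, hub quantile 5% per module, an HGS
    cap of 50 genes, alpha 0.05 for module/DE tests and 0.01 for miRNA ANOVA,
    and integration thresholds |r| >= 0.70 (gene-gene) and 0.50
    (gene-miRNA, negative only; gene-TF, either sign).
    """

    soft_power_grid: list[int] = field(default_factory=lambda: list(range(1, 36)))
    r2_cutoff: float = 0.87
    min_module_size: int = 30
    deep_split: int = 2
    network_type: str = "unsigned"
    hub_quantile: float = 0.05
    hgs_cap: int = 50
    alpha_module: float = 0.05
    alpha_de: float = 0.05
    alpha_mirna: float = 0.01
    thr_gene_gene: float = 0.70
    thr_gene_mirna: float = 0.50
    thr_gene_tf: float = 0.50
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.soft_power_grid:
            raise ValueError("soft_power_grid must be nonempty")
        if any(int(b) != b or b < 1 for b in self.soft_power_grid):
            raise ValueError("soft powers must be integers >= 1")
        if self.network_type not in ("unsigned", "signed"):
            raise ValueError(f"unknown network_type {self.network_type!r}")
        if not 0 <= self.deep_split <= 4:
            raise ValueError("deep_split must be in 0..4")
        for name in ("r2_cutoff", "hub_quantile", "alpha_module", "alpha_de",
                     "alpha_mirna", "thr_gene_gene", "thr_gene_mirna",
                     "thr_gene_tf"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0, 1], got {v}")
        if self.min_module_size < 2:
            raise ValueError("min_module_size must be >= 2")
        if self.hgs_cap < 1:
            raise ValueError("hgs_cap must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        if not isinstance(doc, Mapping):
            raise ValueError("config file must be a flat key/value document")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**doc)

    def to_yaml(self, path) -> None:
        doc = {k: getattr(self, k) for k in self.__dataclass_fields__}
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)
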