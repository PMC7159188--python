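"""Synthetic mRNA/miRNA/TF data with planted, recoverable network structure.

The generator emulates the statistical skeleton of an age-grouped thymic
transcriptome study: ~1,500 genes across 50 samples (5 age groups × 10) with
planted co-expression modules built from a single latent eigengene each, some
of which correlate with binary age-group traits; ~428 miRNAs across a
29-sample subset with a long-tailed abundance distribution (a small abundant
tier sits a knee-gap above the rest) and planted negative miRNA-gene
correlations; and TF profiles covarying with designated partner genes.

Planted correlations are embedded *exactly in sample*: the noise component of
every planted construct is residualized against its target vector and
re-standardized, so the empirical Pearson r of a planted pair equals its
target value at generation time (up to float rounding).  Planted effect sizes
are thereby study conditions, not random draws.  Background features remain
iid Gaussian noise, so null-calibration properties (uniform p-values, ~alpha
false-selection rates) still hold with genuine sampling variability.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import ExpressionMatrix, InteractionTable, SampleMetadata

DEFAULT_MODULE_SIZES = tuple(int(round(s)) for s in np.linspace(30, 120, 15))
#: Three trait-linked modules mirroring the study design: one mid-sized module
#: positively linked to the oldest group, one large module negatively linked
#: to it, and one module negatively linked to the neonate group (and weakly
#: positively to the oldest).  Module indices are 1-based by size rank.
DEFAULT_TRAIT_EFFECTS = (
    (3, "E", -0.34),
    (11, "E", 0.41),
    (12, "A", -0.31),
    (12, "E", 0.30),
)


@dataclass
class SyntheticGroundTruth:
    """Planted structure labels accompanying a simulated dataset."""

    module_of_gene: dict[str, int]  # 0 = background noise gene
    trait_linked_modules: dict[int, list[tuple[str, float]]]
    planted_mirna_edges: list[tuple[str, str, float]]  # (miRNA, gene, rho)
    planted_tf_edges: list[tuple[str, str, float]]  # (TF, gene, rho)
    abundant_mirnas: list[str]
    gene_ids: list[str] = field(default_factory=list)
    mirna_ids: list[str] = field(default_factory=list)
    tf_ids: list[str] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        for mod, effects in self.trait_linked_modules.items():
            for _, rho in effects:
                if abs(rho) > 1:
                    raise ValueError(f"module {mod}: |rho| > 1")
        genes = set(self.module_of_gene)
        for mi, g, _ in self.planted_mirna_edges:
            if g not in genes:
                raise ValueError(f"planted miRNA edge references unknown gene {g!r}")
        for tf, g, _ in self.planted_tf_edges:
            if g not in genes:
                raise ValueError(f"planted TF edge references unknown gene {g!r}")

    def module_labels(self, gene_order: list[str]) -> np.ndarray:
        return np.array([self.module_of_gene[g] for g in gene_order])

    def to_json(self, path) -> None:
        doc = {
            "module_of_gene": self.module_of_gene,
            "trait_linked_modules": {
                str(k): [[t, r] for t, r in v]
                for k, v in self.trait_linked_modules.items()
            },
            "planted_mirna_edges": [list(e) for e in self.planted_mirna_edges],
            "planted_tf_edges": [list(e) for e in self.planted_tf_edges],
            "abundant_mirnas": self.abundant_mirnas,
            "gene_ids": self.gene_ids,
            "mirna_ids": self.mirna_ids,
            "tf_ids": self.tf_ids,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SyntheticGroundTruth":
        with open(path) as fh:
            doc = json.load(fh)
        return cls(
            module_of_gene=doc["module_of_gene"],
            trait_linked_modules={
                int(k): [(t, float(r)) for t, r in v]
                for k, v in doc["trait_linked_modules"].items()
            },
            planted_mirna_edges=[(a, b, float(r))
                                 for a, b, r in doc["planted_mirna_edges"]],
            planted_tf_edges=[(a, b, float(r))
                              for a, b, r in doc["planted_tf_edges"]],
            abundant_mirnas=doc["abundant_mirnas"],
            gene_ids=doc["gene_ids"],
            mirna_ids=doc["mirna_ids"],
            tf_ids=doc["tf_ids"],
            seed=int(doc["seed"]),
        )


def _standardize(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    if sd == 0:
        raise ValueError("cannot standardize a constant vector")
    return (v - v.mean()) / sd


def _orthonormal_noise(rng: np.random.Generator, basis: np.ndarray) -> np.ndarray:
    """Unit-variance Gaussian vector empirically orthogonal to basis columns."""
    n = basis.shape[0]
    z = rng.standard_normal(n)
    design = np.column_stack([np.ones(n), basis]) if basis.size else np.ones((n, 1))
    coef, *_ = np.linalg.lstsq(design, z, rcond=None)
    resid = z - design @ coef
    return _standardize(resid)


def _planted_mixture(rng: np.random.Generator, target: np.ndarray,
                     rho: float) -> np.ndarray:
    """Unit-variance vector with empirical Pearson r(., target) == rho."""
    t = _standardize(target)
    z = _orthonormal_noise(rng, t[:, None])
    return rho * t + np.sqrt(1.0 - rho ** 2) * z


def make_sample_metadata(n_samples: int) -> SampleMetadata:
    """Balanced 5-group design (A-E blocks), genders alternating within group."""
    if n_samples % 5 != 0:
        raise ValueError("n_samples must be divisible into 5 age groups")
    per = n_samples // 5
    rows = []
    for gi, g in enumerate("ABCDE"):
        for k in range(per):
            rows.append({
                "sample_id": f"S{gi * per + k + 1:03d}",
                "age_group": g,
                "gender": "F" if k % 2 == 0 else "M",
                "age_months": [0.5, 3.0, 9.0, 15.0, 24.0][gi],
            })
    return SampleMetadata(pd.DataFrame(rows).set_index("sample_id"))


def _eigengene(rng, meta: SampleMetadata, effects: list[tuple[str, float]]):
    """Latent module eigengene with exact in-sample trait correlations."""
    n = len(meta.sample_ids)
    if not effects:
        return _orthonormal_noise(rng, np.empty((n, 0)))
    t = meta.table
    cols = []
    rhos = []
    for trait, rho in effects:
        if trait == "gender":
            ind = (t["gender"] == "M").astype(float).to_numpy()
        else:
            ind = (t["age_group"] == trait).astype(float).to_numpy()
        cols.append(_standardize(ind))
        rhos.append(rho)
    T = np.column_stack(cols)
    R = (T.T @ T) / n  # empirical correlation of the standardized indicators
    rho_vec = np.array(rhos)
    c = np.linalg.solve(R, rho_vec)
    lam2 = 1.0 - float(rho_vec @ c)
    if lam2 < 0:
        raise ValueError(
            f"infeasible trait correlations {effects}: implied residual "
            f"variance {lam2:.3f} < 0"
        )
    z = _orthonormal_noise(rng, T)
    e = T @ c + np.sqrt(lam2) * z
    return _standardize(e)  # unit variance holds analytically; enforce exactly


def simulate_dataset(
    n_genes: int = 1500,
    n_samples: int = 50,
    module_sizes: tuple[int, ...] | None = None,
    trait_effects: tuple[tuple[int, str, float], ...] = DEFAULT_TRAIT_EFFECTS,
    w_range: tuple[float, float] = (0.5, 0.95),
    noise_sd: float = 1.0,
    mirna_spec: tuple[int, int, float] = (428, 19, 5.3),
    n_mirna_samples: int = 29,
    n_mirna_edges: int = 12,
    mirna_edge_rho: float = -0.6,
    tf_spec: tuple[int, int] = (63, 20),
    tf_edge_rho: float = 0.6,
    na_rate: float = 0.0,
    seed: int = 0,
) -> tuple[ExpressionMatrix, ExpressionMatrix, ExpressionMatrix,
           SampleMetadata, SyntheticGroundTruth]:
    """Simulate (mRNA, miRNA, TF, metadata, ground truth).

    Parameters
    ----------
    module_sizes
        Planted module sizes; module index 1 is the first entry.  Defaults to
        15 modules spanning 30-120 genes (the study's 85-403 range scaled
        down for desk-scale runs).
    trait_effects
        (module_index, trait, rho) triples; a module may carry several traits
        as long as the implied correlation system is feasible.
    w_range
        Per-gene eigengene weights are drawn uniformly from this range; with
        ``noise_sd=1`` the weight equals the gene-eigengene correlation.
    mirna_spec
        (n_mirna, n_abundant, knee_gap): total miRNAs, size of the abundant
        tier, and the log2 location shift separating that tier from the
        long-tailed background (5.3 log2 units ~ 40-fold).
    """
    rng = np.random.default_rng(seed)
    if module_sizes is None:
        # scale the 15 default sizes to the requested gene count, keeping
        # roughly 25% background
        factor = n_genes / 1500.0
        module_sizes = tuple(max(3, int(round(s * factor)))
                             for s in DEFAULT_MODULE_SIZES)
    module_sizes = tuple(int(s) for s in module_sizes)
    if sum(module_sizes) > n_genes:
        raise ValueError(
            f"module sizes sum to {sum(module_sizes)} > n_genes={n_genes}"
        )
    n_mirna, n_abundant, knee_gap = mirna_spec
    if n_abundant > n_mirna:
        raise ValueError("n_abundant exceeds n_mirna")
    if n_mirna_samples > n_samples:
        raise ValueError("n_mirna_samples exceeds n_samples")
    for _, trait, rho in trait_effects:
        if abs(rho) > 1:
            raise ValueError(f"infeasible trait effect rho={rho}")

    meta = make_sample_metadata(n_samples)
    samples = meta.sample_ids
    n = len(samples)

    # --- mRNA: latent-factor modules + pure-noise background -----------------
    effects_by_module: dict[int, list[tuple[str, float]]] = {}
    for mod, trait, rho in trait_effects:
        if not 1 <= mod <= len(module_sizes):
            raise ValueError(f"trait effect references module {mod} "
                             f"outside 1..{len(module_sizes)}")
        effects_by_module.setdefault(mod, []).append((trait, rho))

    gene_ids = [f"G{i + 1:04d}" for i in range(n_genes)]
    X = np.empty((n_genes, n))
    module_of_gene: dict[str, int] = {}
    eigengenes: dict[int, np.ndarray] = {}
    row = 0
    for mod, size in enumerate(module_sizes, start=1):
        e = _eigengene(rng, meta, effects_by_module.get(mod, []))
        eigengenes[mod] = e
        w = rng.uniform(*w_range, size=size)
        for k in range(size):
            eps = _orthonormal_noise(rng, e[:, None])
            X[row] = w[k] * e + np.sqrt(1 - w[k] ** 2) * noise_sd * eps
            module_of_gene[gene_ids[row]] = mod
            row += 1
    for i in range(row, n_genes):
        X[i] = noise_sd * rng.standard_normal(n)
        module_of_gene[gene_ids[i]] = 0
    baseline = rng.uniform(6.0, 12.0, size=n_genes)
    mrna = ExpressionMatrix(pd.DataFrame(
        X + baseline[:, None], index=gene_ids, columns=samples))

    # --- miRNA: long-tailed abundance with an abundant tier ------------------
    per_group = [n_mirna_samples // 5 + (1 if g < n_mirna_samples % 5 else 0)
                 for g in range(5)]
    mirna_samples: list[str] = []
    for g, grp in enumerate("ABCDE"):
        mirna_samples.extend(meta.samples_in_group(grp)[: per_group[g]])
    mirna_ids = [f"miR-{i + 1:03d}" for i in range(n_mirna)]
    abundant = mirna_ids[:n_abundant]
    # background locations uniform on log2 scale (reciprocal-distributed,
    # long-tailed linear intensities); the abundant tier sits knee_gap above
    # the background floor, past the top of the background span
    mu_bg = 3.0 + rng.uniform(0.0, 3.5, size=n_mirna)
    mu = mu_bg.copy()
    # abundant tier: log-evenly spread over ~4 log2 units above the gap, so
    # the sorted linear-intensity curve drops steeply through the whole tier
    # and its knee sits at the tier's lower edge
    mu[:n_abundant] = (3.0 + knee_gap
                       + 4.0 * np.linspace(1.0, 0.0, n_abundant)
                       + rng.uniform(0.0, 0.08, size=n_abundant))

    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    mirna_sample_idx = [samples.index(s) for s in mirna_samples]
    planted_mirna_edges: list[tuple[str, str, float]] = []
    module_genes = [g for g, m in module_of_gene.items() if m != 0]
    partner_pool = rng.permutation(module_genes)
    M = np.empty((n_mirna, len(mirna_samples)))
    n_edges = min(n_mirna_edges, n_abundant, len(partner_pool))
    for j in range(n_mirna):
        if j < n_edges:
            target_gene = str(partner_pool[j])
            target_profile = X[gene_pos[target_gene], mirna_sample_idx]
            M[j] = _planted_mixture(rng, target_profile, mirna_edge_rho)
            planted_mirna_edges.append((mirna_ids[j], target_gene,
                                        float(mirna_edge_rho)))
        else:
            M[j] = rng.standard_normal(len(mirna_samples))
    mirna = ExpressionMatrix(pd.DataFrame(
        0.25 * M + mu[:, None], index=mirna_ids, columns=mirna_samples))

    # --- TFs: profiles covarying with designated partner genes ---------------
    n_tf, n_tf_edges = tf_spec
    tf_ids = [f"TF{i + 1:02d}" for i in range(n_tf)]
    planted_tf_edges: list[tuple[str, str, float]] = []
    tf_partner_pool = rng.permutation(module_genes)
    F = np.empty((n_tf, n))
    n_tf_edges = min(n_tf_edges, n_tf, len(tf_partner_pool))
    for j in range(n_tf):
        if j < n_tf_edges:
            target_gene = str(tf_partner_pool[j])
            rho = tf_edge_rho if j % 2 == 0 else -tf_edge_rho
            F[j] = _planted_mixture(rng, X[gene_pos[target_gene]], rho)
            planted_tf_edges.append((tf_ids[j], target_gene, float(rho)))
        else:
            F[j] = rng.standard_normal(n)
    tf_baseline = rng.uniform(6.0, 12.0, size=n_tf)
    tf = ExpressionMatrix(pd.DataFrame(
        F + tf_baseline[:, None], index=tf_ids, columns=samples))

    if na_rate > 0:
        for m in (mrna, mirna, tf):
            mask = rng.random(m.data.shape) < na_rate
            m.data.values[mask] = np.nan

    truth = SyntheticGroundTruth(
        module_of_gene=module_of_gene,
        trait_linked_modules=effects_by_module,
        planted_mirna_edges=planted_mirna_edges,
        planted_tf_edges=planted_tf_edges,
        abundant_mirnas=abundant,
        gene_ids=gene_ids,
        mirna_ids=mirna_ids,
        tf_ids=tf_ids,
        seed=seed,
    )
    return mrna, mirna, tf, meta, truth


def emit_interaction_fixtures(
    truth: SyntheticGroundTruth,
    n_tf_decoys: int = 0,
    n_mirna_tf_pairs: int = 10,
    seed: int | None = None,
) -> tuple[InteractionTable, InteractionTable]:
    """Derive TF-target and miRNA-TF interaction tables from the ground truth.

    The TF-target table contains every planted TF edge plus ``n_tf_decoys``
    random TF-gene pairs that never duplicate a planted pair; the miRNA-TF
    table pairs abundant miRNAs with TFs as offline "validated" annotations.
    """
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    planted = [(tf, g) for tf, g, _ in truth.planted_tf_edges]
    planted_set = set(planted)
    rows = [{"source": tf, "target": g, "evidence": "planted"}
            for tf, g in planted]
    if n_tf_decoys > 0:
        if not truth.tf_ids or not truth.gene_ids:
            raise ValueError("ground truth lacks feature id lists")
        decoys: set[tuple[str, str]] = set()
        while len(decoys) < n_tf_decoys:
            pair = (str(rng.choice(truth.tf_ids)), str(rng.choice(truth.gene_ids)))
            if pair not in planted_set and pair not in decoys:
                decoys.add(pair)
        rows.extend({"source": tf, "target": g, "evidence": "decoy"}
                    for tf, g in sorted(decoys))
    tf_target = InteractionTable("tf_target", pd.DataFrame(
        rows, columns=["source", "target", "evidence"]))

    mt_pairs: set[tuple[str, str]] = set()
    if truth.abundant_mirnas and truth.tf_ids:
        while len(mt_pairs) < min(
                n_mirna_tf_pairs, len(truth.abundant_mirnas) * len(truth.tf_ids)):
            mt_pairs.add((str(rng.choice(truth.abundant_mirnas)),
                          str(rng.choice(truth.tf_ids))))
    mirna_tf = InteractionTable("mirna_tf", pd.DataFrame(
        [{"source": a, "target": b, "evidence": "validated"}
         for a, b in sorted(mt_pairs)],
        columns=["source", "target", "evidence"]))
    return tf_target, mirna_tf
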