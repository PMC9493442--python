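"""Synthetic glioma-like cohort generator with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes, not real glioma expression distributions:

* bulk expression is a linear mixture of cell-type signature profiles with
  per-sample Dirichlet fractions, TPM-rescaled and perturbed by
  multiplicative log-normal noise;
* two latent archetypes (M2-high vs M2-low) differ in their Dirichlet
  concentration for the M2 macrophage component, giving a two-cluster
  structure in fraction space;
* five designated "index genes" track the M2 fraction linearly on the
  log2(TPM+1) scale with slope ``index_gene_effect``;
* 150 up- and 150 down-regulated "hit genes" shift with the standardized
  M2 fraction by ``hit_effect`` on the log2 scale;
* three fraction replicates are independent noisy views of the same true
  fraction matrix, standing in for three deconvolution algorithms;
* survival is exponential with log-hazard linear in the standardized
  index; censoring is independent uniform;
* binary alterations follow a logistic model in the standardized M2
  fraction for designated features.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from scipy.special import expit

from .io import (
    AlterationMatrix,
    ClinicalTable,
    ExpressionMatrix,
    FractionSet,
    GeneSetCollection,
)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SyntheticCohort",
    "simulate_cohort",
    "nnls_deconvolve",
    "table1_fixtures",
]

INDEX_GENES = ("PIK3R5", "PIK3R6", "ALOX5", "ALOX5AP", "ALOX15B")
M2_CELL_TYPE = "Macrophage_M2"


@dataclass
class SimulationConfig:
    """Tunable parameters of the synthetic cohort.

    Defaults give a cohort with a clear two-archetype structure, index
    genes moderately coupled to the M2 fraction, and survival hazard
    increasing with the index.
    """

    n_genes: int = 1200
    n_samples: int = 160
    n_cell_types: int = 6
    #: Dirichlet concentration per cell type for the M2-high archetype
    dirichlet_alpha_high: tuple = (8.0, 2.0, 2.0, 2.0, 2.0, 2.0)
    #: and for the M2-low archetype (M2 component first)
    dirichlet_alpha_low: tuple = (1.0, 4.0, 4.0, 4.0, 4.0, 4.0)
    #: probability a sample belongs to the M2-high archetype
    archetype_mixing: float = 0.5
    #: fold elevation of marker genes in their own cell type
    signature_strength: float = 8.0
    #: sd of multiplicative log2-scale expression noise
    noise_sigma: float = 0.25
    #: slope of each index gene on f_M2, log2(TPM+1) units per unit fraction
    index_gene_effect: float = 4.0
    #: sd of the index-gene residual noise (log2 scale)
    index_gene_noise: float = 0.5
    n_hit_up: int = 150
    n_hit_dn: int = 150
    #: log2 shift of hit genes per sd of f_M2; hit genes emulate the
    #: top-ranked DEGs of macrophage stimulation experiments, so their
    #: shift dominates the incidental marker-gene signal
    hit_effect: float = 2.0
    #: sd of fraction-replicate noise (per entry, before renormalization)
    fraction_noise: float = 0.02
    #: log hazard ratio per sd of the macro index
    survival_beta: float = 0.8
    baseline_hazard: float = 1.0 / 500.0
    censor_rate: float = 0.3
    #: slope (log-odds per sd of f_M2) for the planted alteration features
    alteration_slope: float = 2.0
    n_alterations: int = 12
    n_planted_alterations: int = 4
    n_pathway_sets: int = 20
    pathway_set_size: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_genes, self.n_samples, self.n_cell_types) < 1:
            raise ValueError("counts must be >= 1")
        if self.n_cell_types > self.n_genes // 10:
            raise ValueError("too few genes per cell type (need n_genes >= 10 * C)")
        for alpha in (*self.dirichlet_alpha_high, *self.dirichlet_alpha_low):
            if alpha <= 0:
                raise ValueError("dirichlet alpha must be > 0")
        if not 0 <= self.censor_rate < 1:
            raise ValueError("censor_rate must be in [0, 1)")
        n_candidates = self.n_genes - self.n_genes // 4 - len(INDEX_GENES)
        if self.n_hit_up + self.n_hit_dn > n_candidates:
            raise ValueError(
                f"n_genes={self.n_genes} leaves only {n_candidates} non-marker "
                f"genes; cannot plant {self.n_hit_up}+{self.n_hit_dn} hit genes"
            )


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    fractions: pd.DataFrame  # cell types x samples, columns sum to 1
    archetypes: pd.Series  # sample -> {"M2-high", "M2-low"}
    index_genes: dict[str, float]  # gene -> slope on f_M2
    hit_up: list[str]
    hit_dn: list[str]
    survival_beta: float
    planted_alterations: list[str]
    signature_matrix: pd.DataFrame = None  # genes x cell types, linear scale
    #: genes reserved as cell-type markers; the subset of the signature
    #: matrix a deconvolution should be run on (hit/index genes violate
    #: the pure mixture model by construction)
    marker_genes: list[str] = field(default_factory=list)


@dataclass
class SyntheticCohort:
    expression: ExpressionMatrix
    fraction_set: FractionSet
    clinical: ClinicalTable
    gene_sets: GeneSetCollection
    alterations: AlterationMatrix
    truth: GroundTruth


def _signature_matrix(cfg: SimulationConfig, rng: np.random.Generator, genes):
    """Linear-scale signature profiles with disjoint marker blocks."""
    C = cfg.n_cell_types
    base = rng.lognormal(mean=2.0, sigma=1.0, size=(cfg.n_genes, C))
    markers_per_type = cfg.n_genes // (4 * C)  # a quarter of genes are markers
    for c in range(C):
        lo = c * markers_per_type
        hi = lo + markers_per_type
        base[lo:hi, c] *= cfg.signature_strength
    return pd.DataFrame(
        base, index=genes, columns=[M2_CELL_TYPE] + [f"CellType{c}" for c in range(1, C)]
    )


def simulate_cohort(cfg: SimulationConfig) -> SyntheticCohort:
    """Generate a full synthetic cohort; byte-reproducible from ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    genes = [f"G{i:05d}" for i in range(cfg.n_genes)]
    # reserve symbols for the five index genes at the end of the matrix
    for i, g in enumerate(INDEX_GENES):
        genes[-(len(INDEX_GENES) - i)] = g
    samples = [f"S{i:04d}" for i in range(cfg.n_samples)]
    cell_types = [M2_CELL_TYPE] + [f"CellType{c}" for c in range(1, cfg.n_cell_types)]

    # --- archetypes and true fractions ------------------------------------
    is_high = rng.random(cfg.n_samples) < cfg.archetype_mixing
    F = np.empty((cfg.n_cell_types, cfg.n_samples))
    a_high = np.asarray(cfg.dirichlet_alpha_high, dtype=float)[: cfg.n_cell_types]
    a_low = np.asarray(cfg.dirichlet_alpha_low, dtype=float)[: cfg.n_cell_types]
    for j in range(cfg.n_samples):
        F[:, j] = rng.dirichlet(a_high if is_high[j] else a_low)
    fractions = pd.DataFrame(F, index=cell_types, columns=samples)
    f_m2 = F[0]
    z_m2 = (f_m2 - f_m2.mean()) / f_m2.std(ddof=0)

    # --- bulk expression ---------------------------------------------------
    S = _signature_matrix(cfg, rng, genes)
    bulk = S.to_numpy() @ F  # genes x samples, linear scale
    bulk *= 1e6 / bulk.sum(axis=0, keepdims=True)  # TPM convention
    if cfg.noise_sigma > 0:
        bulk *= 2.0 ** rng.normal(0.0, cfg.noise_sigma, size=bulk.shape)

    expr = pd.DataFrame(bulk, index=genes, columns=samples)

    # --- hit genes: log2 shift proportional to standardized f_M2 ----------
    non_marker_start = cfg.n_genes // 4  # markers occupy the first quarter
    candidates = [
        g for g in genes[non_marker_start:] if g not in INDEX_GENES
    ]
    picked = rng.choice(len(candidates), size=cfg.n_hit_up + cfg.n_hit_dn, replace=False)
    hit_up = sorted(candidates[i] for i in picked[: cfg.n_hit_up])
    hit_dn = sorted(candidates[i] for i in picked[cfg.n_hit_up:])
    expr.loc[hit_up] = expr.loc[hit_up].to_numpy() * 2.0 ** (cfg.hit_effect * z_m2)
    expr.loc[hit_dn] = expr.loc[hit_dn].to_numpy() * 2.0 ** (-cfg.hit_effect * z_m2)

    # --- index genes: linear in f_M2 on the log2(TPM+1) scale --------------
    a0 = 2.0
    for g in INDEX_GENES:
        noise = rng.normal(0.0, cfg.index_gene_noise, size=cfg.n_samples) if cfg.index_gene_noise > 0 else 0.0
        log_val = np.maximum(a0 + cfg.index_gene_effect * f_m2 + noise, 0.0)
        expr.loc[g] = 2.0 ** log_val - 1.0

    expression = ExpressionMatrix(expr)

    # --- three noisy fraction replicates ----------------------------------
    replicates = {}
    pvalues = {}
    for name in ("algoA", "algoB", "algoC"):
        noisy = F + rng.normal(0.0, cfg.fraction_noise, size=F.shape)
        noisy = np.clip(noisy, 0.0, None)
        col_sums = noisy.sum(axis=0)
        col_sums[col_sums == 0] = 1.0
        noisy /= col_sums
        replicates[name] = pd.DataFrame(noisy, index=cell_types, columns=samples)
        pvalues[name] = pd.Series(rng.uniform(0.0, 0.04, size=cfg.n_samples), index=samples)
    fraction_set = FractionSet(replicates, pvalues)

    # --- macro index and clinical table ------------------------------------
    index_vals = np.log2(expr.loc[list(INDEX_GENES)].to_numpy() + 1.0).mean(axis=0)
    z_index = (index_vals - index_vals.mean()) / index_vals.std(ddof=0)
    hazard = cfg.baseline_hazard * np.exp(cfg.survival_beta * z_index)
    event_time = rng.exponential(1.0 / hazard)
    if cfg.censor_rate > 0:
        # independent uniform censoring calibrated to the target censor rate
        cens_time = rng.uniform(0.0, np.quantile(event_time, 0.9) / cfg.censor_rate * 0.5,
                                size=cfg.n_samples)
    else:
        cens_time = np.full(cfg.n_samples, np.inf)
    os_time = np.minimum(event_time, cens_time)
    os_event = (event_time <= cens_time).astype(int)
    # PFI: an accelerated version of the same latent process
    pfi_scale = rng.uniform(0.4, 0.8)
    pfi_event_time = event_time * pfi_scale
    pfi_time = np.minimum(pfi_event_time, cens_time)
    pfi_event = (pfi_event_time <= cens_time).astype(int)

    # histology crossed with archetype: M2-high samples are half GBM, half
    # LGG; M2-low samples are LGG (clustering then yields Macro1/2/3)
    histology = np.where(
        is_high & (rng.random(cfg.n_samples) < 0.5), "Glioblastoma", "Astrocytoma"
    )
    who_grade = np.where(histology == "Glioblastoma", "IV",
                         np.where(rng.random(cfg.n_samples) < 0.5, "II", "III"))
    subtype = rng.choice(["Classical", "Mesenchymal", "Proneural", "Neural"],
                         size=cfg.n_samples)
    clinical = ClinicalTable(pd.DataFrame({
        "sample_id": samples,
        "histology": histology,
        "who_grade": who_grade,
        "transcriptome_subtype": subtype,
        "os_time": np.round(os_time, 2),
        "os_event": os_event,
        "pfi_time": np.round(pfi_time, 2),
        "pfi_event": pfi_event,
        "age": np.round(rng.normal(50, 12, size=cfg.n_samples), 1),
        "gender": rng.choice(["Male", "Female"], size=cfg.n_samples),
    }))

    # --- gene sets: hit signatures, an M2-marker pathway, random sets ------
    markers_per_type = cfg.n_genes // (4 * cfg.n_cell_types)
    m2_markers = genes[:markers_per_type]
    sets = {
        "HIT_UP": hit_up,
        "HIT_DN": hit_dn,
        "M2_MARKER_PATHWAY": m2_markers,
    }
    pool = [g for g in genes if g not in set(hit_up) | set(hit_dn) | set(m2_markers)]
    for s in range(cfg.n_pathway_sets):
        idx = rng.choice(len(pool), size=cfg.pathway_set_size, replace=False)
        sets[f"RANDOM_SET_{s:02d}"] = [pool[i] for i in idx]
    gene_sets = GeneSetCollection(sets)

    # --- binary alterations -------------------------------------------------
    alt_features = [f"ALT{i:02d}_mutation" for i in range(cfg.n_alterations)]
    planted = alt_features[: cfg.n_planted_alterations]
    alt = np.empty((cfg.n_alterations, cfg.n_samples), dtype=int)
    for i, feat in enumerate(alt_features):
        if feat in planted:
            p = expit(-0.2 + cfg.alteration_slope * z_m2)
        else:
            p = np.full(cfg.n_samples, 0.3)
        alt[i] = rng.random(cfg.n_samples) < p
    alterations = AlterationMatrix(pd.DataFrame(alt, index=alt_features, columns=samples))

    truth = GroundTruth(
        fractions=fractions,
        archetypes=pd.Series(np.where(is_high, "M2-high", "M2-low"), index=samples),
        index_genes={g: cfg.index_gene_effect for g in INDEX_GENES},
        hit_up=hit_up,
        hit_dn=hit_dn,
        survival_beta=cfg.survival_beta,
        planted_alterations=planted,
        signature_matrix=S,
        marker_genes=genes[: (cfg.n_genes // (4 * cfg.n_cell_types)) * cfg.n_cell_types],
    )
    return SyntheticCohort(expression, fraction_set, clinical, gene_sets, alterations, truth)


def nnls_deconvolve(bulk: ExpressionMatrix, signatures: pd.DataFrame) -> pd.DataFrame:
    """Reference-based non-negative least-squares deconvolution.

    Solves, per sample, ``min ||S w - b||_2, w >= 0`` over the signature
    genes and renormalizes the weights to sum to one. A simple stand-in
    for the in-silico immune-fraction tools whose outputs the pipeline
    normally consumes.
    """
    missing = [g for g in signatures.index if g not in bulk.values.index]
    if missing:
        raise ValueError(f"signature genes absent from bulk: {missing[:5]}")
    S = signatures.to_numpy(dtype=float)
    if np.linalg.matrix_rank(S) < S.shape[1]:
        raise ValueError("signature matrix is rank-deficient")
    B = bulk.values.loc[signatures.index].to_numpy(dtype=float)
    out = np.empty((S.shape[1], B.shape[1]))
    for j in range(B.shape[1]):
        if not B[:, j].any():
            import warnings

            warnings.warn(f"sample {bulk.sample_ids[j]!r} is all zero; uniform fractions")
            out[:, j] = 1.0 / S.shape[1]
            continue
        w, _ = nnls(S, B[:, j])
        total = w.sum()
        out[:, j] = w / total if total > 0 else 1.0 / S.shape[1]
    return pd.DataFrame(out, index=signatures.columns, columns=bulk.sample_ids)


#: contingency tables of clinical feature composition between the Macro
#: groups of three glioma cohorts (counts as published); Macro2-vs-Macro3
#: comparisons carry only the two LGG group columns.
_TABLE1 = {
    "tcga_gender": (
        [[88, 85, 98], [44, 66, 73]],
        ["Male", "Female"],
        ["Macro1", "Macro2", "Macro3"],
    ),
    "tcga_histology": (
        [[61, 44], [33, 55], [42, 58]],
        ["Astrocytoma", "Oligoastrocytoma", "Oligodendroglioma"],
        ["Macro2", "Macro3"],
    ),
    "tcga_who": ([[47, 93], [89, 64]], ["WHO II", "WHO III"], ["Macro2", "Macro3"]),
    "rembrandt_gender": (
        [[62, 36, 41], [37, 12, 32]],
        ["Male", "Female"],
        ["Macro1", "Macro2", "Macro3"],
    ),
    "rembrandt_histology": (
        [[23, 12], [12, 31], [2, 1]],
        ["Astrocytoma", "Oligodendroglioma", "Mixed"],
        ["Macro2", "Macro3"],
    ),
    "rembrandt_who": ([[23, 46], [30, 22]], ["WHO II", "WHO III"], ["Macro2", "Macro3"]),
    "cgga_gender": (
        [[58, 64, 21], [36, 42, 15]],
        ["Male", "Female"],
        ["Macro1", "Macro2", "Macro3"],
    ),
    "cgga_histology": (
        [[34, 10], [53, 12], [4, 1], [13, 12], [2, 1]],
        [
            "Astrocytoma",
            "Anaplastic astrocytoma",
            "Oligodendroglioma",
            "Anaplastic oligodendroglioma",
            "Anaplastic oligoastrocytoma",
        ],
        ["Macro2", "Macro3"],
    ),
    "cgga_who": ([[38, 11], [68, 25]], ["WHO II", "WHO III"], ["Macro2", "Macro3"]),
}


def table1_fixtures() -> dict:
    """Published contingency tables of clinical features between Macro groups."""
    from .association import ContingencyTable

    return {
        name: ContingencyTable(np.array(counts), list(rows), list(cols))
        for name, (counts, rows, cols) in _TABLE1.items()
    }
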