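"""Synthetic single-cell counts with group structure and pseudobulk cohorts.

The generator follows the standard parametric model for scRNA-seq counts
popularised by Splatter: gamma-distributed base gene means, per-group
multiplicative differential-expression factors applied to a random subset
of genes, log-normal per-cell library sizes, and Poisson sampling of
counts.  Counts are converted to TPM by column closure (unit gene lengths —
simulated genes carry no length model).

Pseudobulk cohorts mirror the validation design: each case sample averages
the TPM profiles of ``cells_per_sample`` cells drawn with replacement from
the ground-truth cluster (cluster 1), each control sample averages cells
drawn from the remaining clusters.

Default scale is 5,000 cells × 10,000 genes in 10 equal-probability groups
with DE probability 0.1 and a 250 + 250 sample cohort of 100-cell averages;
pass smaller numbers for quick experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, PhenotypeLabels

__all__ = ["SimulationConfig", "SimulatedDataset", "simulate_sc",
           "counts_to_tpm", "simulate_bulk", "simulate_dataset"]


@dataclass
class SimulationConfig:
    """Parameters of the count simulator.

    Gene means are Gamma(``mean_shape``, rate ``mean_rate``); expected
    library size is LogNormal(``library_size_location``,
    ``library_size_scale``) counts per cell.  Each gene is differentially
    expressed in a group with probability ``de_prob``; DE factors are
    exp(|Normal(de_fold_location, de_fold_scale)|), inverted (down-regulated)
    with probability 1/2.  ``dropout_rate`` optionally zeroes counts
    Bernoulli-wise after sampling (off by default).
    """

    n_cells: int = 5000
    n_genes: int = 10000
    n_groups: int = 10
    group_prob: Optional[list[float]] = None  # default: equal
    de_prob: float = 0.1
    de_fold_location: float = 1.0
    de_fold_scale: float = 0.4
    mean_shape: float = 0.6
    mean_rate: float = 0.3
    library_size_location: float = 11.0
    library_size_scale: float = 0.2
    dropout_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1 or self.n_genes < 1 or self.n_groups < 1:
            raise ValueError("n_cells, n_genes and n_groups must be positive")
        if self.group_prob is None:
            self.group_prob = [1.0 / self.n_groups] * self.n_groups
        p = np.asarray(self.group_prob, dtype=float)
        if len(p) != self.n_groups:
            raise ValueError("group_prob length must equal n_groups")
        if (p < 0).any() or (p > 1).any() or not np.isclose(p.sum(), 1.0):
            raise ValueError("group probabilities must be in [0,1] and sum to 1")
        if not 0 <= self.de_prob <= 1:
            raise ValueError("de_prob must be in [0, 1]")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        for name in ("de_fold_scale", "mean_shape", "mean_rate",
                     "library_size_scale"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class SimulatedDataset:
    """Everything one benchmark run needs, with cluster-1 ground truth."""

    sc_counts: np.ndarray
    sc_tpm: ExpressionMatrix
    cluster_labels: np.ndarray  # 1..n_groups per cell
    bulk_tpm: ExpressionMatrix
    bulk_labels: PhenotypeLabels
    ground_truth: np.ndarray  # True where cluster_labels == 1
    config: SimulationConfig = field(repr=False, default=None)


def simulate_sc(config: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    """Simulate a genes × cells count matrix and per-cell cluster labels.

    Returns ``(counts, cluster_labels)`` with labels in 1..n_groups.
    Reproducible given ``config.seed``; group sizes are multinomial with the
    configured probabilities.
    """
    rng = np.random.default_rng(config.seed)
    n_g, n_c, n_k = config.n_genes, config.n_cells, config.n_groups

    base_mean = rng.gamma(shape=config.mean_shape,
                          scale=1.0 / config.mean_rate, size=n_g)
    base_mean = np.maximum(base_mean, 1e-12)

    # per-group multiplicative DE factors on a de_prob fraction of genes
    group_factors = np.ones((n_k, n_g))
    for k in range(n_k):
        is_de = rng.random(n_g) < config.de_prob
        raw = np.exp(np.abs(rng.normal(config.de_fold_location,
                                       config.de_fold_scale, size=n_g)))
        down = rng.random(n_g) < 0.5
        fac = np.where(down, 1.0 / raw, raw)
        group_factors[k, is_de] = fac[is_de]

    cluster_labels = rng.choice(np.arange(1, n_k + 1), size=n_c,
                                p=np.asarray(config.group_prob))
    lib = np.exp(rng.normal(config.library_size_location,
                            config.library_size_scale, size=n_c))

    group_profiles = base_mean[None, :] * group_factors          # k × genes
    group_profiles /= group_profiles.sum(axis=1, keepdims=True)  # proportions

    lam = group_profiles[cluster_labels - 1].T * lib[None, :]    # genes × cells
    counts = rng.poisson(lam).astype(np.int64)
    if config.dropout_rate > 0:
        counts[rng.random(counts.shape) < config.dropout_rate] = 0
    return counts, cluster_labels


def counts_to_tpm(counts: np.ndarray, gene_lengths: Optional[np.ndarray] = None,
                  gene_ids: Optional[list[str]] = None,
                  cell_ids: Optional[list[str]] = None) -> ExpressionMatrix:
    """Column-closure TPM: length-normalised counts scaled to 1e6 per column."""
    counts = np.asarray(counts, dtype=float)
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    if gene_lengths is not None:
        gene_lengths = np.asarray(gene_lengths, dtype=float)
        if (gene_lengths <= 0).any():
            raise ValueError("gene lengths must be positive")
        counts = counts / gene_lengths[:, None]
    colsum = counts.sum(axis=0)
    zero = np.flatnonzero(colsum == 0)
    if zero.size:
        raise ValueError(f"all-zero count column(s) at positions {zero[:5].tolist()}")
    tpm = counts / colsum[None, :] * 1e6
    n_g, n_c = tpm.shape
    genes = gene_ids if gene_ids is not None else [f"gene{i+1}" for i in range(n_g)]
    cells = cell_ids if cell_ids is not None else [f"cell{i+1}" for i in range(n_c)]
    return ExpressionMatrix(pd.DataFrame(tpm, index=genes, columns=cells),
                            kind="single_cell")


def simulate_bulk(sc_tpm: ExpressionMatrix, cluster_labels: np.ndarray,
                  n_case: int = 250, n_control: int = 250,
                  cells_per_sample: int = 100, case_cluster: int = 1,
                  seed: int = 0) -> tuple[ExpressionMatrix, PhenotypeLabels]:
    """Pseudobulk cohort by averaging cells sampled with replacement.

    Case samples (label 1) average ``cells_per_sample`` cells from
    ``case_cluster``; control samples (label 0) average cells from all other
    clusters pooled.
    """
    cluster_labels = np.asarray(cluster_labels)
    if cluster_labels.shape[0] != sc_tpm.shape[1]:
        raise ValueError("cluster_labels length must equal the cell count")
    case_pool = np.flatnonzero(cluster_labels == case_cluster)
    control_pool = np.flatnonzero(cluster_labels != case_cluster)
    if case_pool.size == 0:
        raise ValueError(f"no cells in case cluster {case_cluster}")
    if control_pool.size == 0:
        raise ValueError("no cells outside the case cluster")
    rng = np.random.default_rng(seed)
    values = sc_tpm.data.to_numpy()
    cols, ids, labels = [], [], []
    for i in range(n_case):
        take = rng.choice(case_pool, size=cells_per_sample, replace=True)
        cols.append(values[:, take].mean(axis=1))
        ids.append(f"case{i+1}")
        labels.append(1)
    for i in range(n_control):
        take = rng.choice(control_pool, size=cells_per_sample, replace=True)
        cols.append(values[:, take].mean(axis=1))
        ids.append(f"control{i+1}")
        labels.append(0)
    bulk = ExpressionMatrix(pd.DataFrame(np.column_stack(cols),
                                         index=sc_tpm.gene_ids, columns=ids),
                            kind="bulk")
    return bulk, PhenotypeLabels(ids, np.array(labels))


def simulate_dataset(config: SimulationConfig, n_case: int = 250,
                     n_control: int = 250, cells_per_sample: int = 100,
                     case_cluster: int = 1) -> SimulatedDataset:
    """Full benchmark dataset: cells, TPM, pseudobulk cohort, ground truth."""
    counts, clusters = simulate_sc(config)
    sc_tpm = counts_to_tpm(counts)
    bulk, labels = simulate_bulk(sc_tpm, clusters, n_case=n_case,
                                 n_control=n_control,
                                 cells_per_sample=cells_per_sample,
                                 case_cluster=case_cluster,
                                 seed=config.seed + 1)
    return SimulatedDataset(sc_counts=counts, sc_tpm=sc_tpm,
                            cluster_labels=clusters, bulk_tpm=bulk,
                            bulk_labels=labels,
                            ground_truth=clusters == case_cluster,
                            config=config)
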