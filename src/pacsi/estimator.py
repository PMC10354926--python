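"""Scikit-learn style estimator tying the pipeline together.

:class:`PACSI` is fitted on a bulk expression cohort with binary phenotype
labels and then scores single cells (or spatial spots) by their network
proximity to the phenotype of interest.  Scoring is transductive: the
rank-based cell signatures depend on the whole cell population passed to
:meth:`score_cells` / :meth:`predict`, so cells are scored as one matrix,
not row by row.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .io import ExpressionMatrix, GeneIdMapping, PhenotypeLabels, zscore_by_sample
from .network import (InteractionNetwork, build_coexpression_network,
                      induce_module, largest_connected_component,
                      multi_source_distance_field)
from .proximity import (NullDistribution, ProximityResult, empirical_pvalue,
                        mean_phenotype_field, null_distribution,
                        results_to_frame)
from .signatures import all_signatures, rank_transform

logger = logging.getLogger(__name__)

__all__ = ["PACSI"]


def _as_expression(X, kind: str, feature_names: Optional[Sequence[str]] = None,
                   zscored: bool = False) -> ExpressionMatrix:
    """Coerce input to a genes × columns ExpressionMatrix.

    DataFrames and arrays follow the sklearn orientation (rows = cells or
    samples, columns = genes) and are transposed; ExpressionMatrix inputs
    are taken as-is.
    """
    if isinstance(X, ExpressionMatrix):
        return X
    if isinstance(X, pd.DataFrame):
        df = X.T.copy()
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        return ExpressionMatrix(df.astype(float), kind=kind, zscored=zscored)
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError(f"expected a 2-D matrix, got shape {X.shape}")
    n_obs, n_genes = X.shape
    genes = list(feature_names) if feature_names is not None \
        else [f"g{i}" for i in range(n_genes)]
    if len(genes) != n_genes:
        raise ValueError("feature name count does not match column count")
    prefix = "cell" if kind == "single_cell" else "sample"
    cols = [f"{prefix}{i}" for i in range(n_obs)]
    return ExpressionMatrix(pd.DataFrame(X.T, index=genes, columns=cols),
                            kind=kind, zscored=zscored)


class PACSI(BaseEstimator):
    """Label cells associated with a bulk-cohort phenotype by network proximity.

    For every cell and bulk sample the estimator takes the ``signature_size``
    genes with the highest cross-column relative-abundance rank, maps them
    into the largest connected component of an interaction network, and
    scores each cell by the mean closest-node hop distance between its
    module and the modules of the phenotype-1 bulk samples.  Significance is
    an empirical P value against uniformly drawn size-matched random
    modules; cells with P < ``alpha`` are selected.

    Parameters
    ----------
    signature_size : int, default=150
        Genes per cell/sample signature.
    n_permutations : int, default=100
        Random modules per null distribution.
    alpha : float, default=0.05
        Empirical-P selection threshold.
    network : InteractionNetwork or networkx.Graph, optional
        Interactome.  When None, a co-expression network is built from the
        cell matrix (Pearson p < ``coexpression_alpha``) over the union of
        all signature genes.
    gene_mapping : GeneIdMapping, optional
        Translation of expression gene ids to network node ids.
    coexpression_alpha : float, default=0.05
        Edge threshold for the co-expression fallback.
    null_size_mode : {"in_network", "signature"}, default="in_network"
        Whether random modules match the cell module size after intersection
        with the LCC, or the pre-intersection signature size.
    cache_nulls : bool, default=True
        Share one null distribution among cells with equal module size.
    diagnostics : bool, default=False
        Also report each cell's distance to the phenotype-0 samples.
    random_state : int, optional
        Seed for the permutation test (and nothing else; the pipeline is
        otherwise deterministic).

    Attributes
    ----------
    sample_signatures_ : list of GeneSignature
        Signatures of all bulk samples, in cohort column order.
    positive_ids_ : list of str
        Bulk sample ids labelled 1.
    results_ : pandas.DataFrame
        Per-cell table set by the most recent :meth:`score_cells`.
    lcc_ : InteractionNetwork
        Largest connected component used in the most recent scoring.

    Examples
    --------
    >>> est = PACSI(signature_size=50, n_permutations=100, random_state=0)
    >>> est.fit(bulk_df, y)                      # doctest: +SKIP
    >>> table = est.score_cells(cells_df)        # doctest: +SKIP
    """

    def __init__(self, signature_size: int = 150, n_permutations: int = 100,
                 alpha: float = 0.05,
                 network: Optional[InteractionNetwork] = None,
                 gene_mapping: Optional[GeneIdMapping] = None,
                 coexpression_alpha: float = 0.05,
                 null_size_mode: str = "in_network",
                 cache_nulls: bool = True,
                 diagnostics: bool = False,
                 random_state: Optional[int] = None):
        self.signature_size = signature_size
        self.n_permutations = n_permutations
        self.alpha = alpha
        self.network = network
        self.gene_mapping = gene_mapping
        self.coexpression_alpha = coexpression_alpha
        self.null_size_mode = null_size_mode
        self.cache_nulls = cache_nulls
        self.diagnostics = diagnostics
        self.random_state = random_state

    # ------------------------------------------------------------------ fit
    def fit(self, X, y) -> "PACSI":
        """Fit on the bulk cohort.

        Parameters
        ----------
        X : DataFrame (samples × genes), array, or ExpressionMatrix (genes × samples)
            Bulk expression (TPM/FPKM).
        y : array of {0, 1} aligned with samples, or PhenotypeLabels
            1 marks the phenotype of interest.
        """
        if self.signature_size < 1:
            raise ValueError("signature_size must be >= 1")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if not 0 <= self.alpha <= 1:
            raise ValueError("alpha must be in [0, 1]")
        if self.null_size_mode not in ("in_network", "signature"):
            raise ValueError("null_size_mode must be 'in_network' or 'signature'")

        bulk = _as_expression(X, kind="bulk")
        if isinstance(y, PhenotypeLabels):
            labels = y
        else:
            y = np.asarray(y).astype(int)
            if len(y) != bulk.shape[1]:
                raise ValueError("y length does not match number of bulk samples")
            labels = PhenotypeLabels(bulk.column_ids, y)
        labels.check_against(bulk)

        z = zscore_by_sample(bulk)
        ranks = rank_transform(z)
        self.sample_signatures_ = all_signatures(ranks, k=self.signature_size)
        self.positive_ids_ = labels.positives()
        self.negative_ids_ = [s for s in labels.sample_ids
                              if s not in set(self.positive_ids_)]
        self.n_features_in_ = bulk.shape[0]
        self.feature_names_in_ = np.asarray(bulk.gene_ids, dtype=object)
        self.classes_ = np.array([False, True])
        return self

    # ------------------------------------------------------------- scoring
    def _resolve_network(self, sc: ExpressionMatrix,
                         cell_sigs, sample_sigs) -> InteractionNetwork:
        if self.network is not None:
            net = self.network
            if not isinstance(net, InteractionNetwork):
                net = InteractionNetwork(net)  # accept a bare networkx graph
            return net if net.is_lcc else largest_connected_component(net)
        logger.info("no interaction network supplied; "
                    "building co-expression network from the cell matrix")
        universe: list[str] = []
        for sig in list(cell_sigs) + list(sample_sigs):
            universe.extend(sig.genes)
        net = build_coexpression_network(sc, alpha=self.coexpression_alpha,
                                         gene_universe=universe)
        return net if net.is_lcc else largest_connected_component(net)

    def score_cells(self, X) -> pd.DataFrame:
        """Score a cell population; returns the per-cell results table.

        One row per input cell: ``cell_id``, ``module_size``,
        ``phenotype_distance`` (mean hops), ``empirical_p``, ``selected``.
        Cells whose signature has no node in the LCC get NaN distance/P and
        are never selected.
        """
        check_is_fitted(self, "sample_signatures_")
        sc = _as_expression(X, kind="single_cell",
                            feature_names=list(self.feature_names_in_))
        cell_ranks = rank_transform(sc)
        cell_sigs = all_signatures(cell_ranks, k=self.signature_size)

        lcc = self._resolve_network(sc, cell_sigs, self.sample_signatures_)
        self.lcc_ = lcc

        pos = set(self.positive_ids_)
        pos_modules = []
        n_empty_samples = 0
        for sig in self.sample_signatures_:
            if sig.owner_id not in pos:
                continue
            mod = induce_module(sig, lcc, self.gene_mapping)
            if mod.size == 0:
                n_empty_samples += 1
            else:
                pos_modules.append(mod)
        if n_empty_samples:
            logger.warning("%d phenotype-1 sample module(s) empty after network "
                           "intersection; dropped", n_empty_samples)
        if not pos_modules:
            raise ValueError("no phenotype-1 sample signature maps into the network")

        fields = [multi_source_distance_field(lcc, m) for m in pos_modules]
        mean_field = mean_phenotype_field(fields)

        control_field = None
        if self.diagnostics and self.negative_ids_:
            neg = set(self.negative_ids_)
            neg_modules = [induce_module(s, lcc, self.gene_mapping)
                           for s in self.sample_signatures_ if s.owner_id in neg]
            neg_modules = [m for m in neg_modules if m.size > 0]
            if neg_modules:
                control_field = mean_phenotype_field(
                    [multi_source_distance_field(lcc, m) for m in neg_modules])

        cell_modules = [induce_module(sig, lcc, self.gene_mapping)
                        for sig in cell_sigs]
        node_index = lcc.node_index

        def null_size(mod) -> int:
            return mod.size if self.null_size_mode == "in_network" \
                else mod.original_size

        sizes = sorted({null_size(m) for m in cell_modules if m.size > 0})
        rng = np.random.default_rng(self.random_state)
        nulls: dict[int, NullDistribution] = {}
        for s in sizes:  # ascending order keeps the rng stream reproducible
            nulls[s] = null_distribution(s, fields, lcc,
                                         n_permutations=self.n_permutations,
                                         seed=rng)
        results: list[ProximityResult] = []
        n_empty_cells = 0
        for mod in cell_modules:
            if mod.size == 0:
                n_empty_cells += 1
                results.append(ProximityResult(
                    cell_id=mod.owner_id, phenotype_distance=float("nan"),
                    empirical_p=float("nan"),
                    n_permutations=self.n_permutations, module_size=0,
                    selected=False))
                continue
            idx = [node_index[n] for n in sorted(mod.nodes)]
            dist = float(mean_field[idx].mean())
            if self.cache_nulls:
                null = nulls[null_size(mod)]
            else:
                null = null_distribution(null_size(mod), fields, lcc,
                                         n_permutations=self.n_permutations,
                                         seed=rng)
            p = empirical_pvalue(dist, null)
            ctrl = float(control_field[idx].mean()) if control_field is not None \
                else float("nan")
            results.append(ProximityResult(
                cell_id=mod.owner_id, phenotype_distance=dist, empirical_p=p,
                n_permutations=self.n_permutations, module_size=mod.size,
                selected=bool(p < self.alpha), control_distance=ctrl))
        if n_empty_cells:
            logger.warning("%d cell(s) had empty network modules; reported as NA",
                           n_empty_cells)
        self.proximity_results_ = results
        self.results_ = results_to_frame(results, diagnostics=self.diagnostics)
        self.run_info_ = {
            "n_cells": len(results),
            "n_cells_empty_module": n_empty_cells,
            "n_positive_samples": len(self.positive_ids_),
            "n_positive_modules": len(pos_modules),
            "n_dropped_positive_modules": n_empty_samples,
            "lcc_nodes": lcc.n_nodes,
            "lcc_edges": lcc.n_edges,
        }
        return self.results_

    def decision_function(self, X) -> np.ndarray:
        """Continuous score: negative phenotype distance (higher = closer)."""
        table = self.score_cells(X)
        return -table["phenotype_distance"].to_numpy()

    def predict(self, X) -> np.ndarray:
        """Boolean selection at ``alpha`` (empirical P strictly below)."""
        table = self.score_cells(X)
        return table["selected"].to_numpy(dtype=bool)

    def fit_predict(self, X, y, cells=None) -> np.ndarray:
        """Fit on bulk (X, y) and predict the given cell matrix."""
        if cells is None:
            raise ValueError("fit_predict requires the cell matrix as `cells`")
        return self.fit(X, y).predict(cells)
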