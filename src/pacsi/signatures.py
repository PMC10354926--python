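"""Rank-based relative-abundance matrices and top-k gene signatures.

Each gene row of an expression matrix is replaced by its cross-column ranks
divided by the number of columns, so an entry close to 1 means "this column
expresses the gene more highly than almost every other column".  A column's
signature is the k genes with the largest such relative abundance (k = 150
by default).
"""

from __future__ import annotations

from dataclasses import dataclass
import logging

import numpy as np
import pandas as pd
import scipy.stats

from .io import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = ["RankMatrix", "GeneSignature", "rank_transform", "extract_signature",
           "all_signatures", "DEFAULT_SIGNATURE_SIZE"]

DEFAULT_SIGNATURE_SIZE = 150


@dataclass
class RankMatrix:
    """Per-gene cross-column relative-abundance ranks in (0, 1]."""

    data: pd.DataFrame  # genes × columns, entries r/N with midrank ties

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def column_ids(self) -> list[str]:
        return list(self.data.columns)


@dataclass
class GeneSignature:
    """Top-k relative-abundance genes for one cell or bulk sample."""

    owner_id: str
    genes: list[str]

    @property
    def size(self) -> int:
        return len(self.genes)


def rank_transform(matrix: ExpressionMatrix) -> RankMatrix:
    """Replace each gene row by ranks across columns, divided by N columns.

    Ascending convention: the column with the largest expression of a gene
    gets rank N and value 1.  Ties take the midrank (average of the tied
    positions), so an all-constant row is (N+1)/(2N) everywhere.
    """
    n_cols = matrix.data.shape[1]
    if n_cols < 2:
        raise ValueError("rank transform needs at least 2 columns")
    ranks = scipy.stats.rankdata(matrix.data.to_numpy(), axis=1, method="average")
    return RankMatrix(pd.DataFrame(ranks / n_cols, index=matrix.data.index,
                                   columns=matrix.data.columns))


def _signature_order(ranks: RankMatrix) -> np.ndarray:
    """Row permutation sorting genes by descending rank value per column,
    ties broken by lexicographic gene id.  Returns an array of row indices,
    shape (n_genes, n_columns)."""
    values = ranks.data.to_numpy()
    lex = np.argsort(ranks.data.index.to_numpy(), kind="stable")
    # stable sort of the lexicographically pre-ordered rows keeps id order on ties
    order_within = np.argsort(-values[lex], axis=0, kind="stable")
    return lex[order_within]


def extract_signature(ranks: RankMatrix, column_id: str,
                      k: int = DEFAULT_SIGNATURE_SIZE) -> GeneSignature:
    """The k genes with the largest relative abundance in one column.

    Deterministic tie-break at the cutoff: descending rank value, then
    lexicographic gene id.  If k exceeds the gene count all genes are
    returned with a warning.
    """
    if k < 1:
        raise ValueError("signature size k must be >= 1")
    if column_id not in ranks.data.columns:
        raise KeyError(f"column {column_id!r} not in rank matrix")
    n_genes = ranks.data.shape[0]
    if k > n_genes:
        logger.warning("signature size %d exceeds gene count %d; using all genes",
                       k, n_genes)
        k = n_genes
    col = ranks.data.columns.get_loc(column_id)
    order = _signature_order(ranks)[:, col]
    genes = ranks.data.index.to_numpy()[order[:k]]
    return GeneSignature(owner_id=column_id, genes=list(genes))


def all_signatures(ranks: RankMatrix, k: int = DEFAULT_SIGNATURE_SIZE) -> list[GeneSignature]:
    """One signature per column, in column order."""
    if k < 1:
        raise ValueError("signature size k must be >= 1")
    n_genes = ranks.data.shape[0]
    if k > n_genes:
        logger.warning("signature size %d exceeds gene count %d; using all genes",
                       k, n_genes)
        k = n_genes
    order = _signature_order(ranks)
    gene_arr = ranks.data.index.to_numpy()
    return [GeneSignature(owner_id=col, genes=list(gene_arr[order[:k, j]]))
            for j, col in enumerate(ranks.data.columns)]


def write_signatures(signatures: list[GeneSignature], path) -> None:
    """Two-column TSV export: owner_id, gene_id — one row per member."""
    rows = [(s.owner_id, g) for s in signatures for g in s.genes]
    pd.DataFrame(rows, columns=["owner_id", "gene_id"]).to_csv(
        path, sep="\t", index=False, header=False)
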