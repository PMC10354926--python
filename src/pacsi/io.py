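"""Expression-matrix, phenotype-label and gene-mapping input handling.

Expression data is kept genes × columns (cells or samples), the orientation
bulk RNA-seq and scRNA-seq matrices are distributed in.  Values are expected
to be non-negative abundance units (TPM/FPKM); the only normalisation applied
here is the per-sample z-score used for bulk cohorts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "PhenotypeLabels",
    "GeneIdMapping",
    "load_expression",
    "write_expression",
    "load_labels",
    "load_mapping",
    "zscore_by_sample",
    "map_gene_ids",
]


@dataclass
class ExpressionMatrix:
    """A genes × columns expression table.

    Parameters
    ----------
    data : pandas.DataFrame
        Rows indexed by gene id, columns by cell/sample id.
    kind : {"single_cell", "bulk"}
        What the columns are.
    zscored : bool
        True once :func:`zscore_by_sample` has been applied (negative
        values are then permitted).
    """

    data: pd.DataFrame
    kind: str = "single_cell"
    zscored: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("single_cell", "bulk"):
            raise ValueError(f"kind must be 'single_cell' or 'bulk', got {self.kind!r}")
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids after validation: {dupes[:5]}")
        if self.data.columns.has_duplicates:
            dupes = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate column ids: {dupes[:5]}")
        values = self.data.to_numpy()
        if not np.all(np.isfinite(values)):
            raise ValueError("expression matrix contains non-finite values")
        if not self.zscored and values.size and values.min() < 0:
            raise ValueError("expression matrix contains negative values")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def column_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()


@dataclass
class PhenotypeLabels:
    """Binary phenotype labels (1 = phenotype of interest) for bulk samples."""

    sample_ids: list[str]
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.sample_ids) != len(self.labels):
            raise ValueError("sample_ids and labels differ in length")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids in phenotype labels")
        bad = set(np.unique(self.labels)) - {0, 1}
        if bad:
            raise ValueError(f"labels must be 0/1, found {sorted(bad)}")
        if not ((self.labels == 1).any() and (self.labels == 0).any()):
            raise ValueError("labels must contain at least one 1 and one 0")

    def positives(self) -> list[str]:
        """Sample ids labelled 1 (the phenotype of interest)."""
        return [s for s, l in zip(self.sample_ids, self.labels) if l == 1]

    def check_against(self, bulk: ExpressionMatrix) -> None:
        missing = set(self.sample_ids) - set(bulk.column_ids)
        if missing:
            raise ValueError(
                f"{len(missing)} labelled samples absent from bulk matrix, "
                f"e.g. {sorted(missing)[:3]}"
            )


@dataclass
class GeneIdMapping:
    """Many-to-many gene-symbol → network-identifier translation table."""

    pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen = set()
        clean = []
        for src, tgt in self.pairs:
            if not src or not tgt:
                raise ValueError("mapping pairs must have non-empty ids")
            if (src, tgt) in seen:
                continue
            seen.add((src, tgt))
            clean.append((str(src), str(tgt)))
        self.pairs = clean
        self._by_source: dict[str, list[str]] = {}
        for src, tgt in self.pairs:
            self._by_source.setdefault(src, []).append(tgt)

    def targets_of(self, source: str) -> list[str]:
        return self._by_source.get(source, [])


def _collapse_duplicate_genes(df: pd.DataFrame) -> pd.DataFrame:
    if df.index.has_duplicates:
        n = int(df.index.duplicated().sum())
        logger.info("collapsing %d duplicate gene rows by mean", n)
        df = df.groupby(level=0, sort=False).mean()
    return df


def load_expression(path: str | Path, format: str | None = None,
                    kind: str = "single_cell") -> ExpressionMatrix:
    """Read an expression matrix from MTX (+sidecars), TSV or CSV.

    Dense files carry gene ids in the first column and a header row of
    column ids.  MTX is the genes × columns MatrixMarket triplet format with
    ``genes.tsv`` and ``barcodes.tsv`` sidecar files in the same directory.
    Duplicate gene rows are collapsed by mean and logged.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"expression file not found: {path}")
    if format is None:
        format = {".mtx": "mtx", ".csv": "csv"}.get(path.suffix, "tsv")
    if format == "mtx":
        genes_file = path.parent / "genes.tsv"
        barcodes_file = path.parent / "barcodes.tsv"
        for side in (genes_file, barcodes_file):
            if not side.exists():
                raise FileNotFoundError(f"MTX sidecar missing: {side}")
        try:
            mat = scipy.io.mmread(path)
        except Exception as exc:  # scipy raises bare ValueError on bad files
            raise ValueError(f"malformed MTX file {path}: {exc}") from exc
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        genes = pd.read_csv(genes_file, sep="\t", header=None)[0].astype(str)
        barcodes = pd.read_csv(barcodes_file, sep="\t", header=None)[0].astype(str)
        if mat.shape != (len(genes), len(barcodes)):
            raise ValueError(
                f"MTX shape {mat.shape} does not match sidecars "
                f"({len(genes)} genes, {len(barcodes)} barcodes)"
            )
        df = pd.DataFrame(np.asarray(mat, dtype=float), index=genes, columns=barcodes)
    elif format in ("tsv", "csv"):
        sep = "\t" if format == "tsv" else ","
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split(sep)[1:]
        if len(header) != len(set(header)):
            dupes = sorted({c for c in header if header.count(c) > 1})
            raise ValueError(f"duplicate column ids in {path}: {dupes[:5]}")
        try:
            df = pd.read_csv(path, sep=sep, index_col=0)
        except Exception as exc:
            raise ValueError(f"malformed {format} file {path}: {exc}") from exc
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        df = df.astype(float)
    else:
        raise ValueError(f"unknown format {format!r}")
    df = _collapse_duplicate_genes(df)
    return ExpressionMatrix(df, kind=kind)


def write_expression(matrix: ExpressionMatrix, path: str | Path, format: str = "tsv") -> None:
    """Write a matrix as dense TSV/CSV (genes in first column, header row)."""
    sep = "\t" if format == "tsv" else ","
    matrix.data.to_csv(path, sep=sep)


def load_labels(path: str | Path) -> PhenotypeLabels:
    """Read a two-column (sample_id, label) TSV without header."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"labels file not found: {path}")
    df = pd.read_csv(path, sep="\t", header=None, names=["sample_id", "label"])
    return PhenotypeLabels(df["sample_id"].astype(str).tolist(),
                           df["label"].to_numpy())


def load_mapping(path: str | Path) -> GeneIdMapping:
    """Read a two-column (source_id, target_id) TSV without header."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"mapping file not found: {path}")
    df = pd.read_csv(path, sep="\t", header=None, names=["source", "target"])
    return GeneIdMapping(list(zip(df["source"].astype(str), df["target"].astype(str))))


def zscore_by_sample(bulk: ExpressionMatrix) -> ExpressionMatrix:
    """Standardise each bulk column (sample) to mean 0, sd 1 across genes.

    Uses the population (divide-by-N) standard deviation.  A zero-variance
    column is an error naming the sample.
    """
    values = bulk.data.to_numpy(dtype=float)
    mean = values.mean(axis=0, keepdims=True)
    sd = values.std(axis=0, keepdims=True)  # population sd
    flat = np.flatnonzero(sd.ravel() == 0)
    if flat.size:
        bad = [bulk.column_ids[i] for i in flat[:5]]
        raise ValueError(f"zero-variance sample column(s): {bad}")
    z = (values - mean) / sd
    df = pd.DataFrame(z, index=bulk.data.index, columns=bulk.data.columns)
    return ExpressionMatrix(df, kind=bulk.kind, zscored=True)


def map_gene_ids(genes: Sequence[str] | Iterable[str], mapping: GeneIdMapping | None) -> list[str]:
    """Translate gene ids through a mapping table (set semantics).

    Returns the sorted union of target ids for all source ids present in the
    mapping; unmapped sources are dropped and counted in the log.  With no
    mapping the input is passed through deduplicated.
    """
    genes = list(genes)
    if mapping is None:
        return sorted(set(genes))
    if not mapping.pairs:
        raise ValueError("gene id mapping is empty")
    out: set[str] = set()
    dropped = 0
    for g in genes:
        targets = mapping.targets_of(g)
        if targets:
            out.update(targets)
        else:
            dropped += 1
    if dropped:
        logger.info("map_gene_ids: %d of %d source ids had no mapping", dropped, len(genes))
    return sorted(out)
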