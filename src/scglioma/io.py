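"""Containers and plain-text I/O for the pipeline's standard objects.

The digital gene expression (DGE) matrix lives in an :class:`ExpressionMatrix`
(genes x cells, sparse molecule counts) and round-trips through MatrixMarket
plus sidecar ``genes.tsv`` / ``barcodes.tsv`` name files. Molecule tables and
gene annotations are tab-separated text.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

MOLECULE_COLUMNS = ["barcode", "umi", "gene", "reads"]


@dataclass
class ExpressionMatrix:
    """Genes x cells matrix of deduplicated molecule (UMI) counts."""

    counts: sp.csr_matrix
    genes: pd.Index
    cells: pd.Index

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.genes = pd.Index(self.genes, name="gene")
        self.cells = pd.Index(self.cells, name="cell")
        if self.counts.shape != (len(self.genes), len(self.cells)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.genes)} genes x {len(self.cells)} cells"
            )

    # ---- construction ----
    @classmethod
    def from_dense(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        """From a genes x cells DataFrame."""
        return cls(sp.csr_matrix(frame.to_numpy()), frame.index, frame.columns)

    # ---- basic views ----
    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def dense(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts.toarray(), index=self.genes, columns=self.cells)

    def cell_totals(self) -> pd.Series:
        """Molecules per cell (column sums)."""
        return pd.Series(np.asarray(self.counts.sum(axis=0)).ravel(), index=self.cells)

    def gene_totals(self) -> pd.Series:
        return pd.Series(np.asarray(self.counts.sum(axis=1)).ravel(), index=self.genes)

    def cells_detected_per_gene(self) -> pd.Series:
        """Number of cells with at least one molecule, per gene."""
        det = np.asarray((self.counts > 0).sum(axis=1)).ravel()
        return pd.Series(det, index=self.genes)

    def detection_frequency(self, cell_mask: np.ndarray | None = None) -> pd.Series:
        """Fraction of (selected) cells in which each gene is detected."""
        ind = self.counts > 0
        if cell_mask is not None:
            mask = np.asarray(cell_mask, dtype=bool)
            ind = ind[:, mask]
        n = ind.shape[1]
        if n == 0:
            raise ValueError("detection frequency over an empty cell set")
        return pd.Series(np.asarray(ind.sum(axis=1)).ravel() / n, index=self.genes)

    def cpt(self) -> np.ndarray:
        """Counts per thousand molecules, dense genes x cells float array."""
        totals = np.asarray(self.counts.sum(axis=0)).ravel().astype(float)
        if np.any(totals == 0):
            zero = self.cells[totals == 0].tolist()
            raise ValueError(f"cells with zero molecules: {zero[:5]}")
        return self.counts.toarray() / totals * 1000.0

    # ---- subsetting ----
    def subset_cells(self, cells: Sequence | np.ndarray) -> "ExpressionMatrix":
        if isinstance(cells, np.ndarray) and cells.dtype == bool:
            idx = np.flatnonzero(cells)
        else:
            idx = self.cells.get_indexer(pd.Index(cells))
            if (idx < 0).any():
                raise KeyError("unknown cell identifiers in subset")
        return ExpressionMatrix(self.counts[:, idx], self.genes, self.cells[idx])

    def subset_genes(self, genes: Sequence | np.ndarray) -> "ExpressionMatrix":
        if isinstance(genes, np.ndarray) and genes.dtype == bool:
            idx = np.flatnonzero(genes)
        else:
            idx = self.genes.get_indexer(pd.Index(genes))
            if (idx < 0).any():
                raise KeyError("unknown gene identifiers in subset")
        return ExpressionMatrix(self.counts[idx, :], self.genes[idx], self.cells)

    # ---- disk ----
    def write_mtx(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        scipy.io.mmwrite(str(directory / "matrix.mtx"), sp.coo_matrix(self.counts))
        (directory / "genes.tsv").write_text("\n".join(self.genes) + "\n")
        (directory / "barcodes.tsv").write_text("\n".join(self.cells) + "\n")

    @classmethod
    def read_mtx(cls, directory: str | Path) -> "ExpressionMatrix":
        directory = Path(directory)
        counts = sp.csr_matrix(scipy.io.mmread(str(directory / "matrix.mtx")))
        genes = (directory / "genes.tsv").read_text().splitlines()
        cells = (directory / "barcodes.tsv").read_text().splitlines()
        return cls(counts, pd.Index(genes), pd.Index(cells))


def read_molecule_table(path: str | Path) -> pd.DataFrame:
    """Read a molecule table TSV (columns barcode, umi, gene, reads)."""
    table = pd.read_csv(path, sep="\t", dtype={"barcode": str, "umi": str, "gene": str})
    missing = [c for c in MOLECULE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"molecule table missing columns: {missing}")
    return table[MOLECULE_COLUMNS]


def write_molecule_table(table: pd.DataFrame, path: str | Path) -> None:
    table[MOLECULE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_gene_annotation(path: str | Path) -> pd.DataFrame:
    """Gene annotation TSV: gene, chromosome, is_mito, is_hla."""
    annot = pd.read_csv(path, sep="\t", dtype={"gene": str, "chromosome": str})
    annot = annot.set_index("gene")
    for col in ("is_mito", "is_hla"):
        annot[col] = annot[col].astype(bool)
    return annot


def write_gene_annotation(annot: pd.DataFrame, path: str | Path) -> None:
    annot.to_csv(path, sep="\t", index=True, index_label="gene")


def read_chromosome_counts(path: str | Path) -> pd.Series:
    """Two-column TSV chromosome -> read count (bulk WGS)."""
    frame = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    return frame.set_index("chromosome")["reads"]


def write_chromosome_counts(counts: pd.Series, path: str | Path) -> None:
    counts.rename("reads").to_csv(path, sep="\t", index_label="chromosome")
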