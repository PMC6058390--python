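"""Cell-level quality control.

Four filters remove dead cells and library artifacts: mitochondrial
molecule fraction > 10% and gene-body/exon molecule ratio > 1.5 flag
cells with compromised membranes (retained mitochondrial or nuclear
transcripts); reads per molecule and molecules per gene outside 2.5
standard deviations of the sample mean flag amplification artifacts.
The SD filters are two-sided and the mean/SD are computed once on the
full pre-filter sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ExpressionMatrix

METRIC_COLUMNS = [
    "mito_fraction",
    "genebody_exon_ratio",
    "reads_per_molecule",
    "molecules_per_gene",
]


@dataclass(frozen=True)
class QCThresholds:
    mito_max: float = 0.10
    genebody_exon_max: float = 1.5
    n_sd: float = 2.5


def compute_qc(
    expr: ExpressionMatrix,
    annot: pd.DataFrame,
    table: pd.DataFrame,
    genebody_exon_ratio: pd.Series,
) -> pd.DataFrame:
    """Per-cell QC metrics.

    `table` is the collapsed molecule table (for reads per molecule);
    `genebody_exon_ratio` is supplied externally per cell — it cannot be
    derived from an exon-only expression matrix.
    """
    totals = expr.cell_totals()
    if (totals == 0).any():
        zero = totals.index[totals == 0].tolist()
        raise ValueError(f"cells with zero molecules: {zero[:5]}")

    mito_genes = annot.index[annot["is_mito"]]
    mito_mask = expr.genes.isin(mito_genes)
    mito_counts = pd.Series(
        np.asarray(expr.counts[np.flatnonzero(mito_mask), :].sum(axis=0)).ravel(),
        index=expr.cells,
    )
    mito_fraction = mito_counts / totals

    per_bc = table.groupby("barcode")["reads"].agg(["sum", "size"])
    reads_per_molecule = (per_bc["sum"] / per_bc["size"]).reindex(expr.cells)

    genes_detected = pd.Series(
        np.asarray((expr.counts > 0).sum(axis=0)).ravel(), index=expr.cells
    )
    molecules_per_gene = totals / genes_detected

    metrics = pd.DataFrame(
        {
            "mito_fraction": mito_fraction,
            "genebody_exon_ratio": genebody_exon_ratio.reindex(expr.cells),
            "reads_per_molecule": reads_per_molecule,
            "molecules_per_gene": molecules_per_gene,
        }
    )
    if metrics.isna().any().any():
        bad = metrics.index[metrics.isna().any(axis=1)].tolist()
        raise ValueError(f"incomplete QC metrics for cells: {bad[:5]}")
    return metrics


def filter_cells(
    metrics: pd.DataFrame, thresholds: QCThresholds = QCThresholds()
) -> tuple[pd.Index, pd.DataFrame]:
    """Apply the four QC rules.

    Returns (kept cells, reasons): `reasons` is a boolean frame over the
    removed cells, one column per triggering rule. Mean/SD for the two
    deviation rules come from the full input sample, before any removal
    (population SD, ddof=0).
    """
    if len(metrics) < 3:
        raise ValueError("QC filtering needs at least 3 cells (SD undefined)")
    flags = pd.DataFrame(index=metrics.index)
    flags["mito"] = metrics["mito_fraction"] > thresholds.mito_max
    flags["genebody_exon"] = (
        metrics["genebody_exon_ratio"] > thresholds.genebody_exon_max
    )
    for col in ("reads_per_molecule", "molecules_per_gene"):
        x = metrics[col]
        dev = (x - x.mean()).abs()
        flags[col] = dev > thresholds.n_sd * x.std(ddof=0)
    removed = flags.any(axis=1)
    return metrics.index[~removed], flags.loc[removed]
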