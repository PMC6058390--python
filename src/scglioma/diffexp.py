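"""Detection-frequency differential expression and drop-out analysis.

At shallow sequencing depth the informative signal is whether a gene is
detected at all, not how many molecules are counted, so differential
expression is an exact two-sided binomial test on detection frequencies:
for each gene, the number of in-group cells detecting it is compared
against the out-group detection frequency (pseudocount-stabilized
plug-in rate), with Benjamini-Hochberg correction across genes. The same
machinery drives the pervasiveness ranking (which qualifying gene is
detected most broadly in the transformed compartment) and the drop-out
curve (detection frequency vs. expression, with an isotonic expected
curve whose deviations flag subpopulation-restricted genes).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.isotonic import IsotonicRegression
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix


def binomial_de(expr: ExpressionMatrix, in_group: np.ndarray) -> pd.DataFrame:
    """Two-sided exact binomial test of per-gene detection frequencies.

    `in_group` is a boolean mask over cells. For each gene with k of n
    in-group cells detecting it, the null rate is the out-group plug-in
    q = (k_out + 1)/(n_out + 1) and p = min(1, 2 min(P[X>=k], P[X<=k]))
    for X ~ Binomial(n, q). The fold effect is the ratio of the same
    +1-pseudocount frequencies. This single canonical form backs every
    downstream signature operation.
    """
    mask = np.asarray(in_group, dtype=bool)
    if mask.shape != (len(expr.cells),):
        raise ValueError("in_group mask must have one entry per cell")
    n_in = int(mask.sum())
    n_out = int((~mask).sum())
    if n_in == 0 or n_out == 0:
        raise ValueError("both groups must be non-empty")

    detected = (expr.counts > 0).toarray()
    k_in = detected[:, mask].sum(axis=1)
    k_out = detected[:, ~mask].sum(axis=1)
    q = (k_out + 1) / (n_out + 1)

    p_ge = scipy.stats.binom.sf(k_in - 1, n_in, q)
    p_le = scipy.stats.binom.cdf(k_in, n_in, q)
    pvalue = np.minimum(1.0, 2.0 * np.minimum(p_ge, p_le))
    padj = multipletests(pvalue, method="fdr_bh")[1]
    fold = ((k_in + 1) / (n_in + 1)) / q

    return pd.DataFrame(
        {
            "freq_in": k_in / n_in,
            "freq_out": k_out / n_out,
            "fold": fold,
            "pvalue": pvalue,
            "padj": padj,
        },
        index=expr.genes,
    )


def pervasiveness_rank(
    de: pd.DataFrame, min_fold: float = 8.0, max_padj: float = 0.01
) -> pd.DataFrame:
    """Rank qualifying genes by how broadly they are detected in-group.

    Keeps genes with fold >= `min_fold` and adjusted p < `max_padj`,
    sorts by in-group detection frequency (descending, fold then gene
    name as tie-breaks) and adds the frequency x fold product score.
    """
    hits = de[(de["fold"] >= min_fold) & (de["padj"] < max_padj)].copy()
    hits["product"] = hits["freq_in"] * hits["fold"]
    hits = hits.sort_values(
        by=["freq_in", "fold"], ascending=[False, False], kind="stable"
    )
    return hits


@dataclass
class DropoutCurve:
    """Per-gene expression vs. detection, with an isotonic expected curve.

    `table` columns: mean_cpt, detection_frequency, expected, deviation
    (= expected - observed; positive means detected less often than
    expression predicts, the signature of subpopulation restriction).
    """

    table: pd.DataFrame

    def expected_at(self, mean_cpt: np.ndarray) -> np.ndarray:
        iso = IsotonicRegression(out_of_bounds="clip")
        iso.fit(
            np.log(self.table["mean_cpt"].to_numpy()),
            self.table["detection_frequency"].to_numpy(),
        )
        return iso.predict(np.log(np.asarray(mean_cpt, dtype=float)))


def dropout_curve(
    expr: ExpressionMatrix, cell_mask: np.ndarray | None = None
) -> DropoutCurve:
    """Detection frequency as a function of mean expression (CPT).

    The expected curve is an isotonic (monotone non-decreasing)
    regression of detection frequency on log mean CPT over detected
    genes, evaluated at each gene's own expression.
    """
    sub = expr
    if cell_mask is not None:
        sub = expr.subset_cells(np.asarray(cell_mask, dtype=bool))
    cpt = sub.cpt()
    mean_cpt = pd.Series(cpt.mean(axis=1), index=sub.genes)
    freq = sub.detection_frequency()
    keep = mean_cpt > 0
    mean_cpt, freq = mean_cpt[keep], freq[keep]

    iso = IsotonicRegression(out_of_bounds="clip")
    expected = iso.fit_transform(np.log(mean_cpt.to_numpy()), freq.to_numpy())
    table = pd.DataFrame(
        {
            "mean_cpt": mean_cpt,
            "detection_frequency": freq,
            "expected": expected,
            "deviation": expected - freq.to_numpy(),
        }
    )
    return DropoutCurve(table)
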