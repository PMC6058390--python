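"""Transformed-cell identification from chromosome-scale expression.

Whole-chromosome aneuploidies (chr7 gain, chr10 loss and friends) shift
the average expression of the affected chromosome in every transformed
cell. Each cell's profile is the mean of log2(counts per thousand
molecules + 1) over the retained genes of each of the 22 autosomes
(genes expressed in >= 100 cells, excluding the chr6 HLA block, which is
confounded with myeloid expression). Profiles are z-scored per cell and
decomposed by PCA; the malignancy score is the projection onto the axis
(PC1, PC2, or PC1+PC2) that best separates the clustered cells, oriented
so the aneuploid side is positive. Clusters whose median score exceeds
the midpoint of the two 1-D component means are called transformed.

The same chromosome profiles yield the relative chromosomal-expression
heatmap (transformed cell / average untransformed cell), and a bulk-WGS
companion estimates per-chromosome copy number from read counts against
a diploid germline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.metrics import silhouette_score

from .io import ExpressionMatrix

AUTOSOMES = tuple(str(i) for i in range(1, 23))
MIN_CELLS_PER_GENE = 100
AXES = ("pc1", "pc2", "pc1+pc2")


def chromosome_expression(
    expr: ExpressionMatrix,
    annot: pd.DataFrame,
    min_cells: int = MIN_CELLS_PER_GENE,
) -> pd.DataFrame:
    """Cells x 22 autosomes matrix of mean log2(CPT + 1).

    Depth normalization uses each cell's full molecule total; the gene
    filter (expressed in >= `min_cells` cells, no chr6 HLA genes) applies
    per sample, and X/Y/MT genes never contribute columns.
    """
    missing = expr.genes.difference(annot.index)
    if len(missing):
        raise ValueError(f"annotation missing genes: {missing[:5].tolist()}")
    ann = annot.loc[expr.genes]
    detected_in = expr.cells_detected_per_gene()
    keep = (detected_in >= min_cells) & ~ann["is_hla"].to_numpy()
    log_cpt = np.log2(expr.cpt() + 1.0)  # genes x cells

    profile = np.empty((len(expr.cells), len(AUTOSOMES)))
    chroms = ann["chromosome"].to_numpy()
    keep_arr = keep.to_numpy()
    for ci, c in enumerate(AUTOSOMES):
        rows = np.flatnonzero((chroms == c) & keep_arr)
        if len(rows) == 0:
            raise ValueError(
                f"chromosome {c} has no retained genes "
                f"(expressed in >= {min_cells} cells, non-HLA)"
            )
        profile[:, ci] = log_cpt[rows, :].mean(axis=0)
    return pd.DataFrame(profile, index=expr.cells, columns=list(AUTOSOMES))


def zscore_rows(chrom: pd.DataFrame) -> pd.DataFrame:
    """Per-cell z-score over the 22 chromosome entries."""
    values = chrom.to_numpy(dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, keepdims=True)
    flat = sd.ravel() == 0
    if flat.any():
        cells = chrom.index[flat].tolist()
        raise ValueError(f"constant chromosome profile (zero SD) for cells: {cells[:5]}")
    return pd.DataFrame((values - mean) / sd, index=chrom.index, columns=chrom.columns)


@dataclass
class MalignancyResult:
    scores: pd.Series  # per-cell malignancy score
    axis: str  # "pc1", "pc2", or "pc1+pc2"
    principal_components: pd.DataFrame  # cells x first two PCs
    cluster_medians: pd.Series  # per-cluster median score
    transformed_clusters: tuple  # clusters called transformed
    is_transformed: pd.Series  # per-cell call via its cluster
    loading_kurtosis: float  # chromosome-loading kurtosis of the chosen axis
    burden_correlation: float  # |corr(axis, z-profile kurtosis)| (diagnostic)
    contrast: float  # max |mean z difference| between the two 1-D components
    separation: float  # silhouette of the 1-D two-component split (diagnostic)
    call_threshold: float | None  # midpoint used for the call, if called


def _split_1d(x: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Exact 1-D two-means: best split of the sorted values by within-class
    SSE. Returns (labels, lower mean, upper mean)."""
    order = np.argsort(x, kind="stable")
    xs = x[order]
    n = len(xs)
    csum = np.cumsum(xs)
    csq = np.cumsum(xs**2)
    best_sse, best_i = np.inf, 1
    for i in range(1, n):
        s1, q1 = csum[i - 1], csq[i - 1]
        s2, q2 = csum[-1] - s1, csq[-1] - q1
        sse = (q1 - s1**2 / i) + (q2 - s2**2 / (n - i))
        if sse < best_sse - 1e-15:
            best_sse, best_i = sse, i
    labels = np.zeros(n, dtype=int)
    labels[order[best_i:]] = 1
    m0 = xs[:best_i].mean()
    m1 = xs[best_i:].mean()
    return labels, float(m0), float(m1)


def malignancy_score(
    chrom: pd.DataFrame,
    clusters: pd.Series,
    axis: str = "auto",
    min_contrast: float = 1.5,
) -> MalignancyResult:
    """Score cells along the chromosome-expression axis separating
    aneuploid from euploid cells.

    With axis="auto" the candidate axes PC1, PC2 and PC1+PC2 are ranked
    by the excess kurtosis of their chromosome loading vector: an
    aneuploidy axis concentrates its loading on the few altered
    chromosomes, whereas lineage-expression axes spread small loadings
    over many. The winning axis is oriented so the outlier-heavy
    (aneuploidy-burdened) cells are positive. The transformed call is
    gated on the contrast between the two 1-D score components: their
    mean z-profiles must differ by at least `min_contrast` on some
    chromosome (a whole-chromosome gain/loss moves its z-entry by ~2-3;
    euploid population structure stays near ~1). Below the gate no
    transformed call is made. Caveat: a population whose expression
    program happens to concentrate on one chromosome is indistinguishable
    from dosage by expression alone - the reason bulk WGS backs this
    score up.
    """
    clusters = clusters.reindex(chrom.index)
    if clusters.isna().any():
        raise ValueError("cluster labels missing for some cells")
    if clusters.nunique() < 2:
        raise ValueError(
            "need >= 2 clusters (or include an external untransformed "
            "reference set in the matrix)"
        )
    z = zscore_rows(chrom)
    zmat = z.to_numpy()
    centered = zmat - zmat.mean(axis=0, keepdims=True)
    if np.allclose(centered, 0):
        raise ValueError("constant z-matrix: PCA undefined")
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    pcs = u[:, :2] * s[:2]
    # per-cell aneuploidy burden: dosage shifts put a few extreme entries
    # in an otherwise flat z-profile (used only to orient the axis sign)
    burden = scipy.stats.kurtosis(zmat, axis=1, fisher=True)

    candidates = {
        "pc1": (pcs[:, 0].copy(), vt[0]),
        "pc2": (pcs[:, 1].copy(), vt[1]),
        "pc1+pc2": (pcs[:, 0] + pcs[:, 1], vt[0] * s[0] + vt[1] * s[1]),
    }
    evaluated: dict[str, tuple] = {}
    for name, (vec, loading) in candidates.items():
        v = vec.copy()
        loading = loading / np.linalg.norm(loading)
        load_kurt = float(scipy.stats.kurtosis(loading, fisher=True))
        corr = np.corrcoef(v, burden)[0, 1] if v.std() > 0 else 0.0
        if not np.isfinite(corr):
            corr = 0.0
        if corr < 0:  # orient: aneuploidy-burdened side positive
            v = -v
        if v.std() == 0:
            evaluated[name] = (v, load_kurt, abs(corr), 0.0, -1.0, 0.0, 0.0)
            continue
        labels, m0, m1 = _split_1d(v)
        hi = v >= (m0 + m1) / 2.0
        if hi.all() or not hi.any():
            contrast = 0.0
        else:
            contrast = float(
                np.abs(zmat[hi].mean(axis=0) - zmat[~hi].mean(axis=0)).max()
            )
        if len(np.unique(labels)) < 2:
            evaluated[name] = (v, load_kurt, abs(corr), contrast, -1.0, m0, m1)
            continue
        sil = float(silhouette_score(v.reshape(-1, 1), labels))
        evaluated[name] = (v, load_kurt, abs(corr), contrast, sil, m0, m1)

    if axis == "auto":
        chosen = max(evaluated, key=lambda k: evaluated[k][1])
    elif axis in evaluated:
        chosen = axis
    else:
        raise ValueError(f"axis must be one of {('auto',) + AXES}, got {axis!r}")
    vec, load_kurt, burden_corr, contrast, sil, m0, m1 = evaluated[chosen]

    scores = pd.Series(vec, index=chrom.index, name="malignancy_score")
    medians = scores.groupby(clusters).median()
    if contrast >= min_contrast:
        threshold: float | None = (m0 + m1) / 2.0
        transformed = tuple(medians.index[medians > threshold])
    else:
        threshold = None
        transformed = ()
    is_transformed = clusters.isin(transformed).rename("is_transformed")
    return MalignancyResult(
        scores=scores,
        axis=chosen,
        principal_components=pd.DataFrame(
            pcs, index=chrom.index, columns=["pc1", "pc2"]
        ),
        cluster_medians=medians,
        transformed_clusters=transformed,
        is_transformed=is_transformed,
        loading_kurtosis=load_kurt,
        burden_correlation=burden_corr,
        contrast=contrast,
        separation=sil,
        call_threshold=threshold,
    )


def relative_chromosome_expression(
    chrom: pd.DataFrame,
    transformed_cells: pd.Index,
    untransformed_cells: pd.Index,
) -> pd.DataFrame:
    """Each transformed cell's chromosome mean divided by the average
    untransformed cell's chromosome mean (the heatmap behind the
    single-cell/WGS concordance)."""
    denom = chrom.loc[untransformed_cells].mean(axis=0)
    if (denom == 0).any():
        zero = denom.index[denom == 0].tolist()
        raise ValueError(f"untransformed mean is zero for chromosomes: {zero}")
    return chrom.loc[transformed_cells].div(denom, axis=1)


def wgs_chromosome_copy_number(
    tumor_counts: pd.Series, germline_counts: pd.Series
) -> pd.Series:
    """Bulk copy number per chromosome: the tumor/germline ratio of
    total-normalized read counts, divided by its median over chromosomes
    and multiplied by two."""
    tumor = tumor_counts.reindex(list(AUTOSOMES))
    germ = germline_counts.reindex(list(AUTOSOMES))
    if tumor.isna().any() or germ.isna().any():
        raise ValueError("counts must cover all 22 autosomes")
    if (germ <= 0).any():
        zero = germ.index[germ <= 0].tolist()
        raise ValueError(f"non-positive germline counts for chromosomes: {zero}")
    ratio = (tumor / tumor.sum()) / (germ / germ.sum())
    return (2.0 * ratio / ratio.median()).rename("copy_number")
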