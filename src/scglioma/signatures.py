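"""Reference-profile correlation clustering and signature derivation.

Three procedures: (1) correlate each transformed subpopulation's average
expression profile with a genes x cell-types reference database
(Spearman), keep the reference types whose correlations vary most across
subpopulations (above-median SD), standardize, and hierarchically
cluster both axes — this is what splits neural/ESC-like from
mesenchymal/MSC-like tumors; (2) the contamination-robust tumor-intrinsic
immune signature: genes far more frequently detected in a group of
tumors' transformed cells than in other tumors' transformed cells, minus
every gene more frequently detected in the group tumors' own immune
cells — what survives cannot be ambient cross-contamination; (3) an
external candidate gene set filtered to genes with strong myeloid
specificity in this data set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as hierarchy
import scipy.stats

from .diffexp import binomial_de
from .io import ExpressionMatrix


@dataclass
class ReferenceCorrelationMap:
    correlation: pd.DataFrame  # subpopulations x reference types, Spearman rho
    retained_types: pd.Index  # above-median cross-subpopulation SD
    standardized: pd.DataFrame  # retained, column z-scored
    row_linkage: np.ndarray  # average linkage, Euclidean, over subpopulations
    col_linkage: np.ndarray  # same over retained reference types
    n_shared_genes: int

    def flat_clusters(self, k: int, axis: str = "columns") -> pd.Series:
        """Cut a dendrogram into k flat clusters."""
        if axis == "columns":
            link, index = self.col_linkage, self.standardized.columns
        elif axis == "rows":
            link, index = self.row_linkage, self.standardized.index
        else:
            raise ValueError("axis must be 'rows' or 'columns'")
        labels = hierarchy.fcluster(link, t=k, criterion="maxclust")
        return pd.Series(labels, index=index, name="cluster")


def _spearman_cross(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Spearman correlation between every column of `a` and of `b`
    (shared row index). Constant columns get rho 0 (rank correlation is
    undefined on a flat profile; zero encodes 'uninformative')."""
    ra = scipy.stats.rankdata(a.to_numpy(), axis=0)
    rb = scipy.stats.rankdata(b.to_numpy(), axis=0)
    ra = ra - ra.mean(axis=0, keepdims=True)
    rb = rb - rb.mean(axis=0, keepdims=True)
    sa = np.sqrt((ra**2).sum(axis=0))
    sb = np.sqrt((rb**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (ra.T @ rb) / np.outer(sa, sb)
    rho[~np.isfinite(rho)] = 0.0
    return pd.DataFrame(rho, index=a.columns, columns=b.columns)


def reference_correlation(
    profiles: pd.DataFrame, refdb: pd.DataFrame
) -> ReferenceCorrelationMap:
    """Correlate subpopulation average profiles against a reference DB.

    `profiles`: genes x subpopulations average expression;
    `refdb`: genes x reference cell types. The gene universes are
    intersected. Reference types with a cross-subpopulation correlation
    SD at or below the median are dropped (ties at the median drop), the
    retained columns are z-standardized, and both axes get average-
    linkage hierarchical clustering with a Euclidean metric.
    """
    if profiles.shape[1] < 2:
        raise ValueError("need >= 2 subpopulations (SD across them undefined)")
    shared = profiles.index.intersection(refdb.index)
    if len(shared) < 3:
        raise ValueError("fewer than 3 shared genes between profiles and reference")
    corr = _spearman_cross(profiles.loc[shared], refdb.loc[shared])

    sd = corr.std(axis=0, ddof=0)
    retained = sd.index[sd > sd.median()]
    if len(retained) < 2:
        raise ValueError("fewer than 2 reference types retained by the SD filter")
    kept = corr[retained]
    standardized = (kept - kept.mean(axis=0)) / kept.std(axis=0, ddof=0)

    row_linkage = hierarchy.linkage(
        standardized.to_numpy(), method="average", metric="euclidean"
    )
    col_linkage = hierarchy.linkage(
        standardized.to_numpy().T, method="average", metric="euclidean"
    )
    return ReferenceCorrelationMap(
        correlation=corr,
        retained_types=retained,
        standardized=standardized,
        row_linkage=row_linkage,
        col_linkage=col_linkage,
        n_shared_genes=len(shared),
    )


def average_profiles(
    expr: ExpressionMatrix, labels: pd.Series
) -> pd.DataFrame:
    """Genes x groups average CPT profile (one column per label)."""
    cpt = expr.cpt()
    labels = labels.reindex(expr.cells)
    cols = {}
    for lab in labels.dropna().unique():
        mask = (labels == lab).to_numpy()
        cols[lab] = cpt[:, mask].mean(axis=1)
    return pd.DataFrame(cols, index=expr.genes)


@dataclass
class SignatureGeneSet:
    genes: list[str]
    provenance: pd.DataFrame  # per-candidate statistics and filter outcomes


def contamination_robust_signature(
    expr: ExpressionMatrix,
    cell_info: pd.DataFrame,
    group_tumors: list[str],
    min_fold: float = 10.0,
    max_p: float = 0.01,
) -> SignatureGeneSet:
    """Tumor-intrinsic immune-like signature that ambient contamination
    cannot explain.

    `cell_info` has one row per cell (index aligned with `expr.cells`)
    with columns `tumor` and `compartment` in {"transformed", "immune",
    "other"}. Step 1 keeps genes with raw p < `max_p` and fold >
    `min_fold` for group-tumor transformed cells vs. all other tumors'
    transformed cells. Step 2 removes, for each group tumor that has
    immune cells, every gene detected more frequently in that tumor's
    immune cells than in its transformed cells (a strict, gate-free
    comparison: the filter is deliberately stringent). Group tumors
    without immune cells are skipped.
    """
    info = cell_info.reindex(expr.cells)
    if info[["tumor", "compartment"]].isna().any().any():
        raise ValueError("cell_info must cover every cell with tumor and compartment")
    transformed = info["compartment"].eq("transformed").to_numpy()
    in_group_tumor = info["tumor"].isin(group_tumors).to_numpy()
    if not (transformed & in_group_tumor).any():
        raise ValueError("no transformed cells in the group tumors")
    if not (transformed & ~in_group_tumor).any():
        raise ValueError("no transformed cells outside the group tumors")

    sub = expr.subset_cells(transformed)
    de = binomial_de(sub, in_group_tumor[transformed])
    step1 = de[(de["pvalue"] < max_p) & (de["fold"] > min_fold)]

    provenance = step1.copy()
    provenance["immune_filtered"] = False
    surviving = set(step1.index)
    for tumor in group_tumors:
        in_tumor = info["tumor"].eq(tumor).to_numpy()
        imm_mask = in_tumor & info["compartment"].eq("immune").to_numpy()
        tr_mask = in_tumor & transformed
        if not imm_mask.any():
            continue  # e.g. a tumor with no detected myeloid compartment
        freq_imm = expr.detection_frequency(imm_mask)
        freq_tr = expr.detection_frequency(tr_mask)
        drop = freq_imm > freq_tr
        for g in list(surviving):
            if drop.get(g, False):
                surviving.discard(g)
                provenance.loc[g, "immune_filtered"] = True
    genes = [g for g in step1.index if g in surviving]
    return SignatureGeneSet(genes=genes, provenance=provenance)


def filter_external_signature(
    expr: ExpressionMatrix,
    myeloid_mask: np.ndarray,
    candidates: list[str],
    min_fold: float = 5.0,
    max_fdr: float = 0.01,
) -> list[str]:
    """Intersect an external candidate gene set with the genes showing
    >= `min_fold` myeloid specificity at BH FDR < `max_fdr` in this data
    set; keeps candidate order, and is always a subset of the input."""
    if not candidates:
        return []
    de = binomial_de(expr, np.asarray(myeloid_mask, dtype=bool))
    specific = set(de.index[(de["fold"] >= min_fold) & (de["padj"] < max_fdr)])
    return [g for g in candidates if g in specific]
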