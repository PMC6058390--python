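"""Drop-out-aware gene selection, Spearman k-NN graph, modularity
clustering, and force-directed layout.

Marker genes are those detected in fewer cells than similarly expressed
genes: genes are ordered by mean depth-normalized expression, placed in
bins of 50, and scored as (bin-max detection frequency - own detection
frequency); scores above 0.15 mark informative genes. Cells are then
linked to their k = 20 most Spearman-correlated neighbors over the
marker genes, edges are Jaccard-reweighted by neighborhood overlap
(the Phenograph construction), and the partition comes from Louvain
modularity optimization.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
import scipy.stats

from .io import ExpressionMatrix

DEFAULT_K = 20
MARKER_SCORE_MIN = 0.15
BIN_SIZE = 50


def score_genes(
    expr: ExpressionMatrix,
    bin_size: int = BIN_SIZE,
    score_min: float = MARKER_SCORE_MIN,
) -> pd.DataFrame:
    """Score detected genes by their detection-frequency deficit.

    Columns: mean_normalized (depth-normalized mean expression),
    detection_frequency, bin, score, is_marker. Bins of `bin_size` genes
    are formed in descending mean normalized expression over detected
    genes only; the last bin may be smaller and still uses its own max.
    """
    detection = expr.detection_frequency()
    detected = detection.index[detection > 0]
    if len(detected) < bin_size:
        raise ValueError(
            f"need >= {bin_size} detected genes, got {len(detected)}"
        )
    totals = expr.cell_totals().to_numpy(dtype=float)
    if np.any(totals == 0):
        raise ValueError("cells with zero molecules")
    norm = expr.counts.toarray() / totals  # columns sum to 1
    mean_norm = pd.Series(norm.mean(axis=1), index=expr.genes)[detected]
    det = detection[detected]

    order = np.argsort(-mean_norm.to_numpy(), kind="stable")
    genes_ord = detected[order]
    bins = np.arange(len(genes_ord)) // bin_size
    det_ord = det[genes_ord].to_numpy()
    bin_max = pd.Series(det_ord).groupby(bins).transform("max").to_numpy()
    score = bin_max - det_ord

    return pd.DataFrame(
        {
            "mean_normalized": mean_norm[genes_ord].to_numpy(),
            "detection_frequency": det_ord,
            "bin": bins,
            "score": score,
            "is_marker": score > score_min,
        },
        index=pd.Index(genes_ord, name="gene"),
    )


def select_markers(scores: pd.DataFrame) -> pd.Index:
    return scores.index[scores["is_marker"]]


@dataclass
class CellGraph:
    """Directed k-NN graph over cells with Spearman-correlation weights."""

    cells: pd.Index
    neighbors: np.ndarray  # (n_cells, k) int indices
    correlation: np.ndarray  # (n_cells, n_cells) Spearman rho

    @property
    def k(self) -> int:
        return self.neighbors.shape[1]

    def distance_matrix(self) -> np.ndarray:
        """1 - Spearman correlation; the contract handed to external
        embedding algorithms (e.g. t-SNE)."""
        return 1.0 - self.correlation

    def to_networkx(self) -> nx.Graph:
        """Symmetrized, unweighted adjacency."""
        g = nx.Graph()
        g.add_nodes_from(range(len(self.cells)))
        for i in range(len(self.cells)):
            for j in self.neighbors[i]:
                g.add_edge(i, int(j))
        return g

    def jaccard_graph(self) -> nx.Graph:
        """Phenograph-style reweighting: edge (i, j) weighted by the
        Jaccard index of the two k-neighborhoods."""
        sets = [set(map(int, row)) for row in self.neighbors]
        g = nx.Graph()
        g.add_nodes_from(range(len(self.cells)))
        for i in range(len(self.cells)):
            for j in sets[i]:
                if g.has_edge(i, j):
                    continue
                inter = len(sets[i] & sets[j])
                union = len(sets[i] | sets[j])
                w = inter / union if union else 0.0
                g.add_edge(i, j, weight=w)
        return g


def spearman_matrix(expr: ExpressionMatrix) -> np.ndarray:
    """Cell-by-cell Spearman correlation (ranks over genes, then Pearson).

    Cells with constant expression across all genes have undefined rank
    correlation; their entries are set to 0.
    """
    dense = expr.counts.toarray().astype(float)
    ranks = scipy.stats.rankdata(dense, axis=0)
    sd = ranks.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(ranks, rowvar=False)
    corr = np.atleast_2d(corr)
    bad = sd == 0
    if bad.any():
        corr[bad, :] = 0.0
        corr[:, bad] = 0.0
    np.fill_diagonal(corr, 1.0)
    return corr


def knn_graph(
    expr: ExpressionMatrix,
    k: int = DEFAULT_K,
    markers: pd.Index | None = None,
) -> CellGraph:
    """k nearest neighbors by Spearman correlation over marker genes.

    Ties are broken by cell order; the result is deterministic.
    """
    n = len(expr.cells)
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of cells ({n})")
    sub = expr.subset_genes(markers) if markers is not None else expr
    corr = spearman_matrix(sub)
    neighbors = np.empty((n, k), dtype=int)
    for i in range(n):
        row = corr[i].copy()
        row[i] = -np.inf  # no self-edges
        order = np.argsort(-row, kind="stable")
        neighbors[i] = order[:k]
    return CellGraph(expr.cells, neighbors, corr)


def cluster_cells(graph: CellGraph, seed: int = 0) -> pd.Series:
    """Louvain modularity partition of the Jaccard-weighted graph.

    Labels are integers, re-indexed by each community's smallest cell
    index so the partition is stable up to content, not discovery order.
    """
    g = graph.jaccard_graph()
    communities = nx.community.louvain_communities(g, weight="weight", seed=seed)
    communities = sorted(communities, key=min)
    labels = np.empty(len(graph.cells), dtype=int)
    for lab, comm in enumerate(communities):
        for node in comm:
            labels[node] = lab
    return pd.Series(labels, index=graph.cells, name="cluster")


def force_layout(graph: CellGraph, seed: int = 0) -> pd.DataFrame:
    """Fruchterman-Reingold spring embedding of the symmetrized k-NN
    graph (default parameters, fixed seed). Coordinates are finite; a
    single node lands at the origin."""
    g = graph.to_networkx()
    pos = nx.spring_layout(g, seed=seed)
    coords = np.array([pos[i] for i in range(len(graph.cells))])
    if not np.isfinite(coords).all():
        raise RuntimeError("non-finite layout coordinates")
    return pd.DataFrame(coords, index=graph.cells, columns=["x", "y"])
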