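"""Raw molecule table -> digital gene expression matrix.

Stages, in pipeline order: discard degenerate barcodes (any 'N' or a run
of five or more 'G'); detect and repair truncated 11-nt barcode synthesis
(barcodes with >= 20 apparent molecules whose UMIs end in 'T' more than
90% of the time lose their last base, which becomes the first base of the
UMI, whose trailing 'T' is trimmed); collapse UMIs within Hamming
distance 1 of one another inside a (barcode, gene) group; collapse
Hamming-1 barcode pairs that share >= 75% of their UMI-gene pairs (the
absorbed barcode needs >= 20 pairs); repeat the UMI collapse on corrected
barcodes; call cells at the knee of the cumulative read curve; count
distinct UMIs per (gene, cell).

Collapse direction is deterministic: candidates are processed in
descending read (or pair) abundance with lexicographic tie-break, and a
lower member merges into the highest-priority survivor within distance 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from . import _seq
from .io import MOLECULE_COLUMNS, ExpressionMatrix

TRUNCATION_MIN_MOLECULES = 20
TRUNCATION_MIN_T_FRACTION = 0.9
BARCODE_MIN_PAIRS = 20
BARCODE_MIN_OVERLAP = 0.75


@dataclass
class CollapseReport:
    """Bookkeeping for one pipeline run; reads are conserved across every
    collapse stage, so reads_in == reads_out + degenerate_reads_removed."""

    reads_in: int = 0
    reads_out: int = 0
    degenerate_reads_removed: int = 0
    n_degenerate_removed: int = 0
    n_truncated_corrected: int = 0
    n_umi_collapsed: int = 0
    n_barcodes_merged: int = 0
    n_cells_called: int | None = None
    stages: list[str] = field(default_factory=list)


def _check_table(table: pd.DataFrame) -> None:
    missing = [c for c in MOLECULE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"molecule table missing columns: {missing}")
    if len(table) and (table["reads"] < 1).any():
        raise ValueError("molecule table contains read counts < 1")


def filter_degenerate_barcodes(table: pd.DataFrame) -> pd.DataFrame:
    """Drop records whose barcode contains 'N' or more than four
    consecutive 'G's."""
    _check_table(table)
    bc = table["barcode"]
    bad = bc.str.contains("N", regex=False) | bc.str.contains("GGGGG", regex=False)
    return table.loc[~bad].reset_index(drop=True)


def correct_truncated_barcodes(
    table: pd.DataFrame,
    min_molecules: int = TRUNCATION_MIN_MOLECULES,
    min_t_fraction: float = TRUNCATION_MIN_T_FRACTION,
) -> tuple[pd.DataFrame, int]:
    """Repair barcodes synthesized one base short.

    A truncated barcode's 12th field position is really the UMI's first
    base and every true UMI terminal base is the poly-T tail, so flagged
    barcodes (>= `min_molecules` apparent molecules, terminal-'T' fraction
    strictly above `min_t_fraction`) are cut to 11 nt and their UMIs are
    shifted right by one. Apparent molecules = distinct (UMI, gene) pairs.
    Returns the corrected table and the number of corrected barcodes.
    """
    _check_table(table)
    if not len(table):
        return table.copy(), 0
    pairs = table[["barcode", "umi", "gene"]].drop_duplicates()
    terminal_t = pairs["umi"].str[-1].eq("T")
    per_bc = pd.DataFrame(
        {"n": pairs.groupby("barcode").size(),
         "t_frac": terminal_t.groupby(pairs["barcode"]).mean()}
    )
    flagged = per_bc.index[
        (per_bc["n"] >= min_molecules) & (per_bc["t_frac"] > min_t_fraction)
    ]
    if not len(flagged):
        return table.reset_index(drop=True), 0
    out = table.copy()
    mask = out["barcode"].isin(set(flagged))
    old_bc = out.loc[mask, "barcode"]
    old_umi = out.loc[mask, "umi"]
    out.loc[mask, "umi"] = old_bc.str[-1] + old_umi.str[:-1]
    out.loc[mask, "barcode"] = old_bc.str[:-1]
    out = (
        out.groupby(["barcode", "umi", "gene"], sort=False, as_index=False)["reads"]
        .sum()
    )
    return out, len(flagged)


def _collapse_codes_greedy(
    codes: np.ndarray, reads: np.ndarray, length: int
) -> tuple[np.ndarray, np.ndarray]:
    """Greedy Hamming-1 collapse of one group, already sorted by priority
    (descending reads, ascending code). Returns (survivor mask, new reads)."""
    owner: dict[int, int] = {}
    keep = np.ones(len(codes), dtype=bool)
    new_reads = reads.copy()
    for i, code in enumerate(codes):
        code = int(code)
        if code in owner:
            tgt = owner[code]
            new_reads[tgt] += new_reads[i]
            keep[i] = False
            continue
        owner[code] = i
        for nb in _seq.neighbors1(code, length):
            owner.setdefault(nb, i)
    return keep, new_reads


def collapse_umis(table: pd.DataFrame) -> pd.DataFrame:
    """Merge UMIs within Hamming distance 1 inside each (barcode, gene)
    group; reads of merged UMIs are summed into the surviving record."""
    _check_table(table)
    if not len(table):
        return table.copy()
    lengths = table["umi"].str.len()
    umi_len = int(lengths.iloc[0])
    if (lengths != umi_len).any():
        # lengths may legitimately differ across barcodes only; check per group
        per_group = lengths.groupby(
            [table["barcode"], table["gene"]]
        ).nunique()
        if (per_group > 1).any():
            raise ValueError("UMIs of unequal length within one (barcode, gene) group")
    group_id = pd.MultiIndex.from_arrays(
        [table["barcode"], table["gene"]]
    ).factorize()[0]

    reads = table["reads"].to_numpy(dtype=np.int64)
    # per-length encoding (unequal lengths across groups are fine)
    codes = np.zeros(len(table), dtype=np.uint64)
    for ulen in np.unique(lengths):
        m = (lengths == ulen).to_numpy()
        codes[m] = _seq.encode_array(table["umi"].to_numpy()[m], int(ulen))

    order = np.lexsort((codes, -reads, group_id))
    g_sorted = group_id[order]
    c_sorted = codes[order]
    r_sorted = reads[order]
    len_sorted = lengths.to_numpy()[order]

    keep = np.ones(len(table), dtype=bool)
    new_reads = r_sorted.copy()
    boundaries = np.flatnonzero(np.diff(g_sorted)) + 1
    starts = np.concatenate(([0], boundaries))
    stops = np.concatenate((boundaries, [len(table)]))
    for s, t in zip(starts, stops):
        if t - s == 1:
            continue
        k, nr = _collapse_codes_greedy(
            c_sorted[s:t], new_reads[s:t], int(len_sorted[s])
        )
        keep[s:t] = k
        new_reads[s:t] = nr

    out = table.iloc[order].copy()
    out["reads"] = new_reads
    out = out.loc[keep].reset_index(drop=True)
    return out


def collapse_barcodes(
    table: pd.DataFrame,
    min_pairs: int = BARCODE_MIN_PAIRS,
    min_overlap: float = BARCODE_MIN_OVERLAP,
) -> tuple[pd.DataFrame, int]:
    """Merge Hamming-1 barcode pairs sharing >= 75% of their UMI-gene pairs.

    The absorbed barcode must hold >= `min_pairs` distinct UMI-gene pairs;
    overlap is |intersection| / |smaller set|. The retained barcode is the
    member with more pairs (lexicographically smaller on ties). Returns
    the re-keyed table and the number of merged barcodes.
    """
    _check_table(table)
    if not len(table):
        return table.copy(), 0
    npairs = table.groupby("barcode").size()
    eligible = npairs.index[npairs >= min_pairs]
    if len(eligible) < 2:
        return table.reset_index(drop=True), 0

    # only barcodes with >= min_pairs can absorb or be absorbed: an
    # absorber always has at least as many pairs as its candidate
    sub = table[table["barcode"].isin(set(eligible))]
    pair_sets: dict[str, set[tuple[str, str]]] = {
        bc: set(zip(grp["umi"], grp["gene"]))
        for bc, grp in sub.groupby("barcode")
    }
    ordered = sorted(eligible, key=lambda b: (-npairs[b], b))

    owner: dict[tuple[int, int], str] = {}  # (length, code) -> retained barcode
    mapping: dict[str, str] = {}
    for bc in ordered:
        blen = len(bc)
        code = _seq.encode(bc)
        key = (blen, code)
        merged = False
        if key in owner:
            target = owner[key]
            mine = pair_sets[bc]
            theirs = pair_sets[target]
            overlap = len(mine & theirs) / min(len(mine), len(theirs))
            if overlap >= min_overlap:
                mapping[bc] = target
                theirs |= mine
                merged = True
        if not merged:
            owner.setdefault(key, bc)
            for nb in _seq.neighbors1(code, blen):
                owner.setdefault((blen, nb), bc)
    if not mapping:
        return table.reset_index(drop=True), 0
    out = table.copy()
    out["barcode"] = out["barcode"].map(lambda b: mapping.get(b, b))
    out = (
        out.groupby(["barcode", "umi", "gene"], sort=False, as_index=False)["reads"]
        .sum()
    )
    return out, len(mapping)


def build_dge(table: pd.DataFrame) -> ExpressionMatrix:
    """Count distinct UMIs per (gene, cell barcode)."""
    _check_table(table)
    if not len(table):
        return ExpressionMatrix(
            sp.csr_matrix((0, 0), dtype=np.int64), pd.Index([]), pd.Index([])
        )
    triplets = table[["barcode", "umi", "gene"]].drop_duplicates()
    gene_codes, genes = pd.factorize(triplets["gene"], sort=True)
    cell_codes, cells = pd.factorize(triplets["barcode"], sort=True)
    counts = sp.coo_matrix(
        (np.ones(len(triplets), dtype=np.int64), (gene_codes, cell_codes)),
        shape=(len(genes), len(cells)),
    ).tocsr()
    return ExpressionMatrix(counts, pd.Index(genes), pd.Index(cells))


def call_cells(table: pd.DataFrame, min_barcodes: int = 10) -> set[str]:
    """Cell-containing barcodes from the knee of the cumulative read curve.

    Barcodes are ranked by descending total reads; on the (rank fraction,
    cumulative read fraction) curve, the knee is the point of maximum
    distance to the chord between the first and last points. Every called
    barcode has at least as many reads as every uncalled one. A flat
    curve (all totals equal) has no knee and all barcodes are called.
    """
    _check_table(table)
    totals = table.groupby("barcode")["reads"].sum()
    if len(totals) < min_barcodes:
        raise ValueError(
            f"cell calling needs >= {min_barcodes} barcodes, got {len(totals)}"
        )
    totals = totals.sort_values(ascending=False, kind="stable")
    frac = np.cumsum(totals.to_numpy(dtype=float))
    frac /= frac[-1]
    n = len(totals)
    x = np.arange(1, n + 1) / n
    # distance from each point to the chord through the first and last point
    x0, y0, x1, y1 = x[0], frac[0], x[-1], frac[-1]
    dx, dy = x1 - x0, y1 - y0
    norm = np.hypot(dx, dy)
    dist = np.abs(dy * (x - x0) - dx * (frac - y0)) / norm
    if dist.max() < 1e-9:
        return set(totals.index)
    knee = int(np.argmax(dist))
    cutoff_reads = totals.iloc[knee]
    # monotone: include every barcode tied with the knee barcode's reads
    called = totals.index[totals.to_numpy() >= cutoff_reads]
    return set(called)


def run_molecule_pipeline(
    table: pd.DataFrame, call: bool = True, return_table: bool = False
):
    """Full collapse pipeline: degenerate filter -> truncation correction
    -> UMI collapse -> barcode collapse -> UMI collapse (repeat) ->
    optional cell calling -> DGE.

    Returns (ExpressionMatrix, CollapseReport), plus the collapsed
    molecule table (restricted to called cells) when `return_table` —
    downstream QC wants reads-per-molecule from exactly that table.
    """
    _check_table(table)
    report = CollapseReport(reads_in=int(table["reads"].sum()))

    filtered = filter_degenerate_barcodes(table)
    report.n_degenerate_removed = len(table) - len(filtered)
    report.degenerate_reads_removed = report.reads_in - int(filtered["reads"].sum())
    report.stages.append("degenerate_filter")

    corrected, n_trunc = correct_truncated_barcodes(filtered)
    report.n_truncated_corrected = n_trunc
    report.stages.append("truncation_correction")

    before = len(corrected)
    collapsed = collapse_umis(corrected)
    report.n_umi_collapsed += before - len(collapsed)
    report.stages.append("umi_collapse")

    collapsed, n_merged = collapse_barcodes(collapsed)
    report.n_barcodes_merged = n_merged
    report.stages.append("barcode_collapse")

    before = len(collapsed)
    collapsed = collapse_umis(collapsed)
    report.n_umi_collapsed += before - len(collapsed)
    report.stages.append("umi_collapse_repeat")

    report.reads_out = int(collapsed["reads"].sum())

    if call:
        cells = call_cells(collapsed)
        collapsed = collapsed[collapsed["barcode"].isin(cells)]
        report.n_cells_called = len(cells)
        report.stages.append("cell_calling")

    if return_table:
        return build_dge(collapsed), report, collapsed.reset_index(drop=True)
    return build_dge(collapsed), report
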