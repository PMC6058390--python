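"""Brute-force reference implementations used only by tests.

These re-derive the collapse and testing rules from their definitions
with naive data structures (string Hamming loops, pmf summation), kept
deliberately independent of the package's vectorized/code-packed paths.
"""

from __future__ import annotations

import math


def hamming(a: str, b: str) -> int:
    assert len(a) == len(b)
    return sum(x != y for x, y in zip(a, b))


def umi_collapse_oracle(group: list[tuple[str, int]]) -> dict[str, int]:
    """Greedy Hamming-1 collapse of one (barcode, gene) group by the
    documented order: descending reads, lexicographic ties; each item
    merges into the earliest-accepted survivor within distance 1."""
    order = sorted(group, key=lambda x: (-x[1], x[0]))
    survivors: list[list] = []
    for umi, reads in order:
        target = None
        for s in survivors:
            if hamming(s[0], umi) <= 1:
                target = s
                break
        if target is None:
            survivors.append([umi, reads])
        else:
            target[1] += reads
    return {u: r for u, r in survivors}


def barcode_collapse_oracle(
    barcodes: dict[str, set], min_pairs: int = 20, min_overlap: float = 0.75
) -> dict[str, str]:
    """Barcode merge map (absorbed -> retained) by the documented order:
    only barcodes with >= min_pairs pairs participate; candidates are
    processed by descending pair count (lexicographic ties) and merge
    into the earliest-accepted Hamming-1 survivor when the pair-set
    overlap (relative to the smaller set) reaches min_overlap."""
    eligible = [b for b in barcodes if len(barcodes[b]) >= min_pairs]
    order = sorted(eligible, key=lambda b: (-len(barcodes[b]), b))
    retained: list[str] = []
    sets = {b: set(barcodes[b]) for b in eligible}
    mapping: dict[str, str] = {}
    for bc in order:
        target = None
        for r in retained:
            if len(r) == len(bc) and hamming(r, bc) <= 1:
                target = r
                break
        if target is not None:
            mine, theirs = sets[bc], sets[target]
            if len(mine & theirs) / min(len(mine), len(theirs)) >= min_overlap:
                mapping[bc] = target
                theirs |= mine
                continue
        retained.append(bc)
    return mapping


def binomial_p_oracle(k: int, n: int, q: float) -> float:
    """Two-sided exact binomial p by direct pmf summation."""
    pmf = [math.comb(n, i) * (q**i) * ((1 - q) ** (n - i)) for i in range(n + 1)]
    p_ge = sum(pmf[k:])
    p_le = sum(pmf[: k + 1])
    return min(1.0, 2.0 * min(p_ge, p_le))


def bh_oracle(pvalues: list[float]) -> list[float]:
    """Benjamini-Hochberg adjusted p-values by the textbook recursion."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adj = [0.0] * m
    running = 1.0
    for rank_from_end, i in enumerate(reversed(order)):
        rank = m - rank_from_end
        running = min(running, pvalues[i] * m / rank)
        adj[i] = running
    return adj
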