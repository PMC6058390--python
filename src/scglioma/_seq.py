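"""Nucleotide-sequence helpers: 2-bit packed codes and Hamming arithmetic.

Sequences over {A, C, G, T} are packed into integers, two bits per base,
most-significant base first, so lexicographic order of strings equals
numeric order of codes (A < C < G < T matches ASCII order).
"""

from __future__ import annotations

import numpy as np

_BASES = "ACGT"
_BASE_TO_BITS = {b: i for i, b in enumerate(_BASES)}


def encode(seq: str) -> int:
    code = 0
    for ch in seq:
        code = (code << 2) | _BASE_TO_BITS[ch]
    return code


def decode(code: int, length: int) -> str:
    out = []
    for pos in range(length):
        out.append(_BASES[(code >> (2 * (length - 1 - pos))) & 3])
    return "".join(out)


def encode_array(seqs: np.ndarray, length: int) -> np.ndarray:
    """Vectorized 2-bit packing of equal-length sequences."""
    joined = "".join(seqs.tolist())
    raw = np.frombuffer(joined.encode("ascii"), dtype=np.uint8).reshape(-1, length)
    lut = np.zeros(256, dtype=np.uint64)
    for b, v in _BASE_TO_BITS.items():
        lut[ord(b)] = v
    bits = lut[raw]
    code = np.zeros(len(seqs), dtype=np.uint64)
    for pos in range(length):
        code = (code << np.uint64(2)) | bits[:, pos]
    return code


def decode_array(codes: np.ndarray, length: int) -> np.ndarray:
    codes = np.asarray(codes, dtype=np.uint64)
    chars = np.empty((len(codes), length), dtype=np.uint8)
    base_ascii = np.frombuffer(_BASES.encode("ascii"), dtype=np.uint8)
    for pos in range(length):
        shift = np.uint64(2 * (length - 1 - pos))
        chars[:, pos] = base_ascii[(codes >> shift) & np.uint64(3)]
    return chars.view(f"S{length}").ravel().astype(str)


def hamming(code_a: int, code_b: int) -> int:
    """Hamming distance between two equal-length packed codes."""
    x = int(code_a) ^ int(code_b)
    # collapse each 2-bit slot to a single set bit
    y = (x | (x >> 1)) & 0x5555555555555555
    return bin(y).count("1")


def hamming_str(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("Hamming distance undefined for unequal lengths")
    return sum(1 for x, y in zip(a, b) if x != y)


def neighbors1(code: int, length: int) -> list[int]:
    """All packed codes at Hamming distance exactly 1 from `code`."""
    out = []
    code = int(code)
    for pos in range(length):
        shift = 2 * pos
        cur = (code >> shift) & 3
        for alt in range(4):
            if alt != cur:
                out.append((code & ~(3 << shift)) | (alt << shift))
    return out


def random_codes(rng: np.random.Generator, n: int, length: int) -> np.ndarray:
    """n random packed codes of the given length (uniform, with replacement)."""
    return rng.integers(0, 4**length, size=n, dtype=np.uint64)


def spaced_codes(
    rng: np.random.Generator,
    n: int,
    length: int,
    min_dist: int = 3,
    forbidden: str | None = "GGGG",
) -> np.ndarray:
    """n distinct packed codes with pairwise Hamming distance >= min_dist.

    Rejection sampling; suitable for barcode pools far below saturation.
    Codes containing the `forbidden` substring are rejected (bead barcode
    sets avoid long G runs, which read as synthesis failures).
    """
    chosen: list[int] = []
    # `taken` holds the Hamming ball of radius (min_dist - 1) around every
    # accepted code; a candidate outside all balls is >= min_dist from all.
    taken: set[int] = set()
    while len(chosen) < n:
        cand = int(rng.integers(0, 4**length, dtype=np.uint64))
        if cand in taken:
            continue
        if forbidden and forbidden in decode(cand, length):
            continue
        ball = {cand}
        for _ in range(min_dist - 1):
            for nb in list(ball):
                ball.update(neighbors1(nb, length))
        chosen.append(cand)
        taken.update(ball)
    return np.array(chosen, dtype=np.uint64)
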