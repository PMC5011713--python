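"""Nucleotide string <-> integer-code helpers shared across modules.

Codes: A=0, C=1, G=2, T=3, N=4.  N never matches any base, including
another N, in every comparison the package performs.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGTN"
N_CODE = 4

_LUT = np.full(256, N_CODE, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _LUT[ord(_b)] = _i
    _LUT[ord(_b.lower())] = _i

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string as a uint8 code array."""
    return _LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return "".join(BASES[c] for c in codes)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def hamming_identity(a: np.ndarray, b: np.ndarray) -> float:
    """Fraction of aligned positions with identical non-N bases."""
    if len(a) == 0:
        return 0.0
    m = (a == b) & (a != N_CODE)
    return float(np.count_nonzero(m)) / len(a)


def trim_weak_ends(agreement: np.ndarray, pivot: float = 0.7) -> tuple[int, int]:
    """Bounds (lo, hi) after trimming terminal runs of weakly supported
    alignment columns.

    From each end the cumulative sum of (agreement - pivot) is tracked; the
    trim point is where it is most negative, so a run of random flank
    columns is removed even when a single column in it agrees by chance.
    """
    n = len(agreement)
    lo, cum, best = 0, 0.0, 0.0
    for j in range(n):
        cum += agreement[j] - pivot
        if cum < best:
            best, lo = cum, j + 1
    hi, cum, best = n, 0.0, 0.0
    for j in range(n - 1, lo - 1, -1):
        cum += agreement[j] - pivot
        if cum < best:
            best, hi = cum, j
    return lo, hi


def kmer_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """All k-mer integer codes of a sequence (Horner encoding, base 4).

    Returns (kmer_code_array, valid_mask); windows containing N are invalid.
    """
    n = len(codes)
    if n < k:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    x = codes.astype(np.int64)
    out = np.zeros(n - k + 1, dtype=np.int64)
    for j in range(k):
        out = out * 4 + np.minimum(x[j : j + n - k + 1], 3)
    is_n = (codes == N_CODE).astype(np.int32)
    cs = np.concatenate([[0], np.cumsum(is_n)])
    window_n = cs[k:] - cs[: n - k + 1]
    return out, window_n == 0
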