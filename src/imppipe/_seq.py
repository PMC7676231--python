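"""Low-level nucleotide encoding shared by the mapping and marker stages.

Bases are packed as uint8 codes A=0, C=1, G=2, T=3; anything else becomes 4
and never matches. 31-mers are folded into uint64 integers (4**31 < 2**63)
so seed lookup reduces to a sorted-array search.
"""

from __future__ import annotations

import numpy as np

KMER_K = 31

_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i
    _ENCODE[ord(chr(_b).lower())] = _i

_DECODE = np.frombuffer(b"ACGT", dtype=np.uint8)

_KMER_WEIGHTS = (4 ** np.arange(KMER_K, dtype=np.uint64)).astype(np.uint64)


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string as a uint8 code array."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def encode_many(seqs: list[str]) -> np.ndarray:
    """Encode equal-length sequences as a (n, L) uint8 matrix."""
    if not seqs:
        return np.empty((0, 0), dtype=np.uint8)
    L = len(seqs[0])
    if any(len(s) != L for s in seqs):
        raise ValueError("encode_many requires equal-length sequences")
    joined = "".join(seqs).encode("ascii")
    return _ENCODE[np.frombuffer(joined, dtype=np.uint8)].reshape(len(seqs), L)


def decode(codes: np.ndarray) -> str:
    if np.any(codes > 3):
        raise ValueError("cannot decode non-ACGT codes")
    return _DECODE[codes].tobytes().decode("ascii")


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    """Reverse-complement along the last axis; non-ACGT codes stay invalid."""
    out = codes[..., ::-1].copy()
    acgt = out < 4
    out[acgt] = 3 - out[acgt]
    return out


def revcomp(seq: str) -> str:
    return decode(revcomp_codes(encode(seq)))


def kmer_codes(codes: np.ndarray, k: int = KMER_K) -> tuple[np.ndarray, np.ndarray]:
    """Integer codes of all k-mers of a 1-D code array.

    Returns (codes_u64, valid) where valid marks windows free of non-ACGT.
    """
    if codes.ndim != 1:
        raise ValueError("expected a 1-D code array")
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool)
    win = np.lib.stride_tricks.sliding_window_view(codes, k)
    vals = win.astype(np.uint64) @ _KMER_WEIGHTS[:k]
    valid = win.max(axis=1) < 4
    return vals, valid


def kmer_codes_at(matrix: np.ndarray, pos: int, k: int = KMER_K) -> np.ndarray:
    """Integer k-mer codes of matrix[:, pos:pos+k] (one per row)."""
    win = matrix[:, pos : pos + k]
    return win.astype(np.uint64) @ _KMER_WEIGHTS[:k]
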