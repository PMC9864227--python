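"""Canonical k-mer extraction and hashing.

Sequences are 2-bit encoded; a k-mer and its reverse complement are collapsed
to the lexicographically smaller integer (the canonical form), so strandedness
never affects sketching or read assignment. Windows containing any non-ACGT
base are dropped. Hashing uses the splitmix64 finalizer, which is deterministic
across processes (unlike Python's string hash).
"""

from __future__ import annotations

import numpy as np

_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i  # lower case


def encode(seq: str) -> np.ndarray:
    """2-bit encode a nucleotide string; non-ACGT bases become the sentinel 4."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _rolling(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, np.uint64), np.empty(0, bool)
    vals = np.zeros(n, np.uint64)
    valid = np.ones(n, bool)
    for i in range(k):
        c = codes[i : i + n]
        vals = (vals << np.uint64(2)) | (c & np.uint8(3)).astype(np.uint64)
        valid &= c < 4
    return vals, valid


def canonical_kmers(seq: str, k: int) -> np.ndarray:
    """All valid canonical k-mers of ``seq`` as uint64 integers, in order."""
    if k < 1 or k > 31:
        raise ValueError("k must be in [1, 31]")
    codes = encode(seq)
    fwd, valid = _rolling(codes, k)
    rc_codes = (3 - codes[::-1].astype(np.int16)).astype(np.uint8)
    rev, _ = _rolling(rc_codes, k)
    canon = np.minimum(fwd, rev[::-1])
    return canon[valid]


def splitmix64(x: np.ndarray) -> np.ndarray:
    """Deterministic 64-bit mix of an uint64 array (splitmix64 finalizer)."""
    x = x.astype(np.uint64, copy=True)
    x += np.uint64(0x9E3779B97F4A7C15)
    x ^= x >> np.uint64(30)
    x *= np.uint64(0xBF58476D1CE4E5B9)
    x ^= x >> np.uint64(27)
    x *= np.uint64(0x94D049BB133111EB)
    x ^= x >> np.uint64(31)
    return x


def hashed_kmers(seq: str, k: int) -> np.ndarray:
    """Unique hashed canonical k-mers of a sequence."""
    return np.unique(splitmix64(canonical_kmers(seq, k)))
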