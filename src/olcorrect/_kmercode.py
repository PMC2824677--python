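"""Vectorized 2-bit k-mer encoding shared by the overlapper and the read mapper."""

from __future__ import annotations

import numpy as np

_ENCODE = np.full(256, 4, dtype=np.uint8)
for i, base in enumerate(b"ACGT"):
    _ENCODE[base] = i


def encode_bases(seq: str) -> np.ndarray:
    """DNA string -> uint8 array with A=0, C=1, G=2, T=3, anything else 4."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def forward_codes(arr: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Integer codes of all forward k-mers of a base array (Horner scheme).

    Returns (codes, valid) where ``valid[i]`` is False if the window contains
    a non-ACGT base.  Requires k <= 31.
    """
    if k > 31:
        raise ValueError("k must be <= 31 for 2-bit packing")
    n = arr.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool)
    safe = np.where(arr > 3, 0, arr).astype(np.uint64)
    codes = np.zeros(n, dtype=np.uint64)
    for i in range(k):
        codes = codes * np.uint64(4) + safe[i : i + n]
    is_n = (arr > 3).astype(np.int32)
    cum = np.concatenate(([0], np.cumsum(is_n)))
    valid = (cum[k:] - cum[:-k]) == 0
    return codes, valid


def canonical_codes(arr: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Canonical (min of strands) k-mer codes for every position.

    Returns (codes, is_forward, valid); ``is_forward[i]`` is True where the
    forward k-mer is the canonical one (ties count as forward).
    """
    fwd, valid = forward_codes(arr, k)
    rc_arr = np.where(arr[::-1] > 3, 4, 3 - arr[::-1]).astype(np.uint8)
    rc_all, _ = forward_codes(rc_arr, k)
    rc = rc_all[::-1]  # rc[i] = code of revcomp of the k-mer at position i
    is_forward = fwd <= rc
    codes = np.where(is_forward, fwd, rc)
    return codes, is_forward, valid
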