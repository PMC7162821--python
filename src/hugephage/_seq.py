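"""Low-level nucleotide utilities shared across modules.

Sequences are plain upper-case ACGT strings at the API surface; internally
they are encoded as ``uint8`` arrays (A=0, C=1, G=2, T=3) so that window
counting, k-mer hashing and Hamming scans vectorize.
"""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

_ENC = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENC[_b] = _i
for _i, _b in enumerate(b"acgt"):
    _ENC[_b] = _i

_DEC = np.frombuffer(b"ACGT", dtype=np.uint8)

BASES = "ACGT"


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode ACGT string to a uint8 array (A=0, C=1, G=2, T=3).

    Characters outside ACGT (case-insensitive) raise ``ValueError``; the
    toolkit does not handle ambiguity codes.
    """
    arr = _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if arr.size and arr.max() > 3:
        bad = chr(np.frombuffer(seq.encode("ascii"), dtype=np.uint8)[arr > 3][0])
        raise ValueError(f"non-ACGT character {bad!r} in sequence")
    return arr


def decode(arr: np.ndarray) -> str:
    return _DEC[arr].tobytes().decode("ascii")


def revcomp_arr(arr: np.ndarray) -> np.ndarray:
    return (3 - arr)[::-1]


def kmer_ids(arr: np.ndarray, k: int) -> np.ndarray:
    """Base-4 integer id of every k-mer (uint64); requires k <= 31."""
    if k > 31:
        raise ValueError("k must be <= 31 to fit in uint64")
    n = arr.size
    if n < k:
        return np.empty(0, dtype=np.uint64)
    ids = np.zeros(n - k + 1, dtype=np.uint64)
    for j in range(k):
        ids = ids * np.uint64(4) + arr[j : n - k + 1 + j].astype(np.uint64)
    return ids


def hamming_scan(target: np.ndarray, query: np.ndarray) -> np.ndarray:
    """Mismatch count of ``query`` against every window of ``target``.

    Returns an int array of length ``len(target) - len(query) + 1``;
    empty if the query is longer than the target.
    """
    m = query.size
    if target.size < m:
        return np.empty(0, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(target, m)
    return np.count_nonzero(windows != query, axis=1)


def window_base_counts(arr: np.ndarray, window: int, step: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-window G and C counts over full windows only.

    Returns ``(starts, counts)`` where counts has shape (n_windows, 2)
    holding G then C counts.
    """
    n = arr.size
    if n < window:
        return np.empty(0, dtype=np.int64), np.empty((0, 2), dtype=np.int64)
    starts = np.arange(0, n - window + 1, step)
    cg = np.cumsum(arr == 2)
    cc = np.cumsum(arr == 1)

    def _wsum(cum: np.ndarray) -> np.ndarray:
        hi = cum[starts + window - 1]
        lo = np.where(starts > 0, cum[starts - 1], 0)
        return hi - lo

    counts = np.stack([_wsum(cg), _wsum(cc)], axis=1)
    return starts, counts
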