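"""Independent brute-force oracles used to verify the fast implementations.

Everything here is deliberately naive (quadratic scans, full enumeration,
pure-Python arithmetic) and shares no code with the package beyond the
sequence-encoding helpers.
"""

from __future__ import annotations

import numpy as np

_COMP = str.maketrans("ACGT", "TGCA")


def revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


def best_end_overlap(seq: str, min_overlap: int, max_overlap: int) -> int | None:
    """Longest k with seq[:k] == seq[-k:], checked for every k."""
    best = None
    for k in range(min_overlap, min(max_overlap, len(seq) // 2) + 1):
        if seq[:k] == seq[-k:]:
            best = k
    return best


def _runs(eq: np.ndarray, min_len: int):
    diff = np.diff(np.concatenate(([0], eq.view(np.int8), [0])))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    for s, e in zip(starts, ends):
        if e - s >= min_len:
            yield int(s), int(e - s)


def direct_repeats(seq: str, min_len: int) -> set:
    """All maximal exact direct repeat pairs, by full diagonal scan."""
    a = np.frombuffer(seq.encode(), dtype=np.uint8)
    n = a.size
    out = set()
    for d in range(1, n):
        if n - d < min_len:
            break
        eq = a[: n - d] == a[d:]
        for s, ln in _runs(eq, min_len):
            out.add((s, s + d, ln))
    return out


def inverted_repeats(seq: str, min_len: int) -> set:
    """All maximal exact inverted (reverse-complement) repeat pairs."""
    a = np.frombuffer(seq.encode(), dtype=np.uint8)
    rc = np.frombuffer(revcomp(seq).encode(), dtype=np.uint8)
    n = a.size
    out = set()
    for d in range(-n + 1, n):
        lo, hi = max(0, -d), min(n, n - d)
        if hi - lo < min_len:
            continue
        eq = a[lo:hi] == rc[lo + d: hi + d]
        for s, ln in _runs(eq, min_len):
            s1 = lo + s
            s2 = n - (s1 + d) - ln
            out.add((min(s1, s2), max(s1, s2), ln))
    return out


def hamming_occurrences(spacer: str, target: str, max_mm: int) -> list:
    """Every window of both strands within max_mm mismatches."""
    out = []
    L = len(spacer)
    for strand, q in (("+", spacer), ("-", revcomp(spacer))):
        for s in range(len(target) - L + 1):
            mm = sum(a != b for a, b in zip(target[s: s + L], q))
            if mm <= max_mm:
                out.append((s, strand, mm))
    return sorted(out)


STOPS = {"code11": {"TAA", "TAG", "TGA"}, "TAG_recoded": {"TAA", "TGA"},
         "TGA_recoded": {"TAA", "TAG"}, "code6_like": {"TGA"}}
STARTS = {"ATG", "GTG", "TTG"}


def six_frame_orfs(seq: str, code: str, min_len_codons: int) -> list:
    """Maximal ORFs on both strands: (start, end, strand) forward axis.

    Walks every frame codon by codon; an ORF runs from the first start
    codon after a stop through the next stop codon inclusive.
    """
    stops = STOPS[code]
    out = []
    n = len(seq)
    for strand in "+-":
        s = seq if strand == "+" else revcomp(seq)
        for frame in range(3):
            start = None
            for i in range(frame, n - 2, 3):
                codon = s[i: i + 3]
                if codon in stops:
                    if start is not None and (i + 3 - start) // 3 >= min_len_codons:
                        lo, hi = start, i + 3
                        if strand == "-":
                            lo, hi = n - hi, n - lo
                        out.append((lo, hi, strand))
                    start = None
                elif start is None and codon in STARTS:
                    start = i
    return out


def greedy_resolve(cands: list) -> list:
    """Longest-first non-overlapping selection, ties leftmost then +."""
    chosen = []
    for lo, hi, strand in sorted(
            cands, key=lambda c: (-(c[1] - c[0]), c[0], 0 if c[2] == "+" else 1)):
        if all(hi <= a or lo >= b for a, b, _ in chosen):
            chosen.append((lo, hi, strand))
    return sorted(chosen)


def reference_mcl(nodes: list, weights: dict, inflation: float = 2.0,
                  max_iter: int = 200, tol: float = 1e-8) -> list:
    """Plain-Python Markov clustering (no pruning) as an independent check.

    ``weights`` maps unordered node pairs to edge weights; self-loops are
    the maximum incident weight (1 for isolated nodes), following the
    canonical MCL formulation.
    """
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    m = [[0.0] * n for _ in range(n)]
    for (a, b), w in weights.items():
        i, j = idx[a], idx[b]
        m[i][j] = max(m[i][j], w)
        m[j][i] = max(m[j][i], w)
    for i in range(n):
        inc = max(m[i]) if any(m[i]) else 0.0
        m[i][i] = inc if inc > 0 else 1.0

    def norm(mat):
        for j in range(n):
            s = sum(mat[i][j] for i in range(n))
            if s:
                for i in range(n):
                    mat[i][j] /= s
        return mat

    m = norm(m)
    for _ in range(max_iter):
        sq = [[sum(m[i][k] * m[k][j] for k in range(n)) for j in range(n)]
              for i in range(n)]
        new = norm([[sq[i][j] ** inflation for j in range(n)] for i in range(n)])
        delta = max(abs(new[i][j] - m[i][j]) for i in range(n) for j in range(n))
        m = new
        if delta < tol:
            break
    owner = {}
    attractors = [i for i in range(n) if m[i][i] > 1e-9]
    for i in attractors:
        for j in range(n):
            if m[i][j] > 1e-9:
                cur = owner.get(j)
                if cur is None or m[i][j] > m[cur][j] or (
                        m[i][j] == m[cur][j] and i < cur):
                    owner[j] = i
    clusters: dict[int, list] = {}
    for j in range(n):
        clusters.setdefault(owner.get(j, j), []).append(nodes[j])
    return sorted([sorted(c) for c in clusters.values()])
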