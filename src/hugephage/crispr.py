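"""CRISPR array detection, spacer-protospacer matching and the
phage-host / phage-phage interaction network.

Array detection is a CRT/MinCED-style seed-and-extend scan: exact 8-mers
recurring at an admissible period seed a candidate repeat, which is
extended while all copies agree and then walked outward collecting
further repeat copies (allowing one mismatch per copy). Spacer matching
is an ungapped Hamming scan of both strands, which makes the
"<= k mismatches" retention rules exact and directly checkable against a
brute-force oracle:

* strict tier: alignment length > 24 bp and <= 1 mismatch;
* expanded tier: once an array has a strict match to a target sequence,
  all of that array's spacers are rescanned against that target allowing
  up to 3 mismatches.

Interaction edges collapse retained matches per (array-owner, target)
pair; edges backed by at least one strict match are drawn solid, edges
with only 2-3-mismatch support dashed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _seq
from .records import ContigRecord


@dataclass
class CrisprArray:
    contig_id: str
    start: int
    end: int
    repeats: list  # (start, seq) per repeat copy
    spacers: list  # (start, seq) per spacer
    consensus_repeat: str
    orientation: str = "unknown"  # repeat-degeneracy orientation not called

    @property
    def n_repeats(self) -> int:
        return len(self.repeats)

    def spacer_ids(self) -> list:
        return [f"{self.contig_id}_{self.start}_sp{i + 1}"
                for i in range(len(self.spacers))]


@dataclass
class SpacerMatch:
    spacer_id: str
    array_key: tuple  # (contig_id, array start)
    source_contig: str
    target_contig: str
    target_start: int
    strand: str
    align_len: int
    mismatches: int
    tier: str  # strict | expanded


@dataclass
class InteractionEdge:
    source: str
    target: str
    n_strict: int
    n_expanded: int
    style: str  # solid | dashed
    self_targeting: bool = False


# ---------------------------------------------------------------------------
# Array detection
# ---------------------------------------------------------------------------

def _consensus(copies: list[str]) -> str:
    length = max(len(c) for c in copies)
    cols = []
    for i in range(length):
        bases = [c[i] for c in copies if i < len(c)]
        # per-column majority, ties by base order
        cols.append(max(sorted(set(bases)), key=bases.count))
    return "".join(cols)


def _count_mm(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _find_next_copy(seq: str, repeat: str, lo: int, hi: int,
                    max_mm: int = 1, direction: int = 1) -> int | None:
    """Best occurrence of ``repeat`` starting in [lo, hi); None if > max_mm.

    ``direction`` controls tie-breaking: +1 prefers the occurrence nearest
    ``lo`` (rightward walk), -1 the one nearest ``hi`` (leftward walk), so
    the array walk never skips a repeat copy when two periods fit in the
    admissible spacer window.
    """
    best, best_mm = None, max_mm + 1
    L = len(repeat)
    rng_ = range(max(lo, 0), min(hi, len(seq) - L + 1))
    for s in (rng_ if direction > 0 else reversed(rng_)):
        mm = _count_mm(seq[s: s + L], repeat)
        if mm < best_mm:
            best, best_mm = s, mm
            if mm == 0:
                break
    return best


def _core(repeat: str) -> tuple[str, int]:
    """Repeat with up to two columns shaved off each end.

    Walking matches against the core so that a boundary shifted by a
    couple of bases (a seed-extension artifact) cannot consume the
    one-mismatch-per-copy budget and stall the walk; the true boundaries
    are restored later from all copies.
    """
    t = min(2, max(0, (len(repeat) - 15) // 2))
    return repeat[t: len(repeat) - t], t


def _walk(seq: str, repeat: str, copies: list[int], smin: int,
          smax: int) -> list[int]:
    """Collect further repeat copies left and right of ``copies``."""
    L = len(repeat)
    core, t = _core(repeat)
    copies = sorted(copies)
    while True:
        base = copies[-1] + L
        nxt = _find_next_copy(seq, core, base + smin + t, base + smax + t + 1)
        if nxt is None:
            break
        copies.append(nxt - t)
    while True:
        base = copies[0]
        prv = _find_next_copy(seq, core, base - smax - L + t,
                              base - smin - L + t + 1, direction=-1)
        if prv is None:
            break
        copies.insert(0, prv - t)
    return copies


def _fill_gaps(seq: str, repeat: str, copies: list[int], smin: int) -> list[int]:
    """Insert repeat copies the walk may have stepped over.

    A seed pair can span two periods (when a flanking base happens to
    match two copies downstream), leaving an intermediate copy out; any
    gap wide enough for another repeat plus minimal spacers is searched
    and filled.
    """
    L = len(repeat)
    core, t = _core(repeat)
    changed = True
    while changed:
        changed = False
        for i in range(len(copies) - 1):
            a, b = copies[i], copies[i + 1]
            if b - (a + L) < smin + L + smin:
                continue
            mid = _find_next_copy(seq, core, a + L + smin + t,
                                  b - L - smin + t + 1)
            if mid is not None:
                copies.insert(i + 1, mid - t)
                changed = True
                break
    return copies


def _refine_boundaries(seq: str, copies: list[int], L: int, rmin: int,
                       rmax: int, smin: int, keep_frac: float = 0.9) -> tuple[list[int], int]:
    """Adjust repeat boundaries using every collected copy.

    The initial repeat is extended from just two seed copies, so a
    coincidental shared flanking base can shift it by a position or two.
    Columns with less than ``keep_frac`` agreement across all copies are
    trimmed; unanimous flanking columns are pulled in (while spacers stay
    within bounds), restoring the maximal consistent repeat.
    """
    nc = len(copies)

    def agree(positions):
        col = [seq[p] for p in positions if 0 <= p < len(seq)]
        if len(col) < nc:
            return 0.0
        return max(col.count(b) for b in set(col)) / nc

    def min_spacer(cs, ln):
        return min(b - a - ln for a, b in zip(cs, cs[1:]))

    # Trim to the longest run of well-agreeing columns. A chance flanking
    # match in the two seed copies can bury a disagreeing column one or
    # two positions in, so every column is scored, not just the edges.
    good = [agree([c + k for c in copies]) >= keep_frac for k in range(L)]
    best = (0, L)  # fall back to the original bounds
    run_start = None
    best_len = 0
    for k, g in enumerate(good + [False]):
        if g and run_start is None:
            run_start = k
        elif not g and run_start is not None:
            if k - run_start > best_len:
                best_len = k - run_start
                best = (run_start, k)
            run_start = None
    i, j = best
    # a boundary correction, not a re-segmentation: shifts beyond a few
    # columns mean the disagreement is interior (a degenerate copy), and
    # the original bounds are kept
    if best_len >= rmin and i <= 4 and L - j <= 4:
        copies = [c + i for c in copies]
        L = j - i
    # Pull in unanimous flanking columns (maximal consistent repeat).
    while (L < rmax and copies[0] > 0 and agree([c - 1 for c in copies]) == 1.0
           and min_spacer(copies, L) - 1 >= smin):
        copies = [c - 1 for c in copies]
        L += 1
    while (L < rmax and copies[-1] + L < len(seq)
           and agree([c + L for c in copies]) == 1.0
           and min_spacer(copies, L) - 1 >= smin):
        L += 1
    return copies, L


def detect_arrays(contig: ContigRecord, min_repeats: int = 3,
                  repeat_len: tuple = (19, 48), spacer_len: tuple = (17, 72),
                  seed_k: int = 8) -> list[CrisprArray]:
    """Detect CRISPR arrays de novo.

    Exact ``seed_k``-mers recurring at a period compatible with one
    repeat + one spacer seed a candidate; the repeat is extended while the
    two seed copies agree, then further copies are collected left and
    right (<= 1 mismatch per copy, spacer length within bounds). Arrays
    with at least ``min_repeats`` repeat copies are reported, trimmed to
    the span of their repeats. Phage arrays are typically compact (the
    source study found a median of six repeats per array).
    """
    seq = contig.seq
    arr = _seq.encode(seq)
    n = arr.size
    rmin, rmax = repeat_len
    smin, smax = spacer_len
    period_lo, period_hi = rmin + smin, rmax + smax
    ids = _seq.kmer_ids(arr, seed_k)
    order = np.argsort(ids, kind="stable")
    s = ids[order]
    eq = s[1:] == s[:-1]
    cp1 = order[:-1][eq]
    cp2 = order[1:][eq]
    gap = cp2 - cp1
    keep = (gap >= period_lo) & (gap <= period_hi)
    seeds = sorted(zip(cp1[keep].tolist(), cp2[keep].tolist()))

    claimed = np.zeros(n, dtype=bool)
    arrays: list[CrisprArray] = []
    for p1, p2 in seeds:
        if claimed[p1]:
            continue
        # extend the exact seed match into a candidate repeat
        lo1, lo2 = p1, p2
        while lo1 > 0 and arr[lo1 - 1] == arr[lo2 - 1]:
            lo1 -= 1; lo2 -= 1
        hi1, hi2 = p1 + seed_k, p2 + seed_k
        while hi1 < lo2 and hi2 < n and arr[hi1] == arr[hi2]:
            hi1 += 1; hi2 += 1
        rep_len = hi1 - lo1
        if rep_len > rmax:  # trim overly long extensions symmetrically
            trim = rep_len - rmax
            lo1 += trim // 2; lo2 += trim // 2
            hi1 = lo1 + rmax; hi2 = lo2 + rmax
            rep_len = rmax
        if rep_len < rmin:
            continue
        spacer = lo2 - hi1
        if not smin <= spacer <= smax:
            continue
        repeat = seq[lo1:hi1]
        L = rep_len
        copies = [lo1, lo2]
        # The seed repeat may be shifted by a base or two (flanking
        # coincidences), which can stall the walk; iterating
        # walk -> gap-fill -> boundary-refine to a fixed point lets the
        # corrected repeat pick up the copies a shifted seed missed.
        for _ in range(4):
            copies = _walk(seq, repeat, copies, smin, smax)
            copies = _fill_gaps(seq, repeat, copies, smin)
            if len(copies) < 2:
                break
            copies, L = _refine_boundaries(seq, copies, L, rmin, rmax, smin)
            new_repeat = seq[copies[0]: copies[0] + L]
            if new_repeat == repeat:
                break
            repeat = new_repeat
        if len(copies) < min_repeats:
            continue
        if claimed[copies[0]: copies[-1] + L].any():
            continue
        claimed[copies[0]: copies[-1] + L] = True
        repeats = [(c, seq[c: c + L]) for c in copies]
        spacers = [(c + L, seq[c + L: copies[i + 1]])
                   for i, c in enumerate(copies[:-1])]
        arrays.append(CrisprArray(
            contig_id=contig.id, start=copies[0], end=copies[-1] + L,
            repeats=repeats, spacers=spacers,
            consensus_repeat=_consensus([r[1] for r in repeats])))
    arrays.sort(key=lambda a: a.start)
    return arrays


# ---------------------------------------------------------------------------
# Spacer matching
# ---------------------------------------------------------------------------

class _TargetIndex:
    """Sorted k-mer indices of target contigs, built lazily per (contig, k)."""

    def __init__(self, targets: list[ContigRecord]):
        self.arrs = {t.id: _seq.encode(t.seq) for t in targets}
        self._cache: dict = {}

    def lookup(self, tid: str, piece: np.ndarray) -> np.ndarray:
        k = piece.size
        key = (tid, k)
        if key not in self._cache:
            ids = _seq.kmer_ids(self.arrs[tid], k)
            order = np.argsort(ids, kind="stable")
            self._cache[key] = (ids[order], order)
        sids, order = self._cache[key]
        pid = np.uint64(0)
        for b in piece:
            pid = pid * np.uint64(4) + np.uint64(b)
        lo = np.searchsorted(sids, pid, side="left")
        hi = np.searchsorted(sids, pid, side="right")
        return order[lo:hi]


def _scan_one(spacer: str, tid: str, index: _TargetIndex, max_mm: int) -> list[tuple]:
    """All ungapped occurrences of ``spacer`` with <= max_mm mismatches.

    Exact by the pigeonhole principle: the spacer is cut into
    ``max_mm + 1`` non-overlapping pieces, at least one of which must
    occur exactly in any window within ``max_mm`` mismatches; candidate
    windows from exact piece lookups are verified by Hamming distance.
    Returns (target_start, strand, mismatches) on the forward axis.
    """
    t = index.arrs[tid]
    out = []
    npieces = max_mm + 1
    for strand, q in (("+", _seq.encode(spacer)),
                      ("-", _seq.revcomp_arr(_seq.encode(spacer)))):
        L = q.size
        k = L // npieces
        cand: set[int] = set()
        for pi in range(npieces):
            off = pi * k
            for p in index.lookup(tid, q[off: off + k]):
                s = int(p) - off
                if 0 <= s <= t.size - L:
                    cand.add(s)
        for s in sorted(cand):
            mm = int(np.count_nonzero(t[s: s + L] != q))
            if mm <= max_mm:
                out.append((s, strand, mm))
    return out


def scan_spacer(spacer: str, target: ContigRecord,
                max_mm: int = 1) -> list[tuple]:
    """All ungapped occurrences of one spacer in one target.

    Returns ``(target_start, strand, mismatches)`` tuples on the forward
    axis; equivalent to a brute-force Hamming scan of both strands.
    """
    return sorted(_scan_one(spacer, target.id, _TargetIndex([target]), max_mm))


def match_spacers(arrays: list[CrisprArray], targets: list[ContigRecord],
                  min_align_len: int = 25, strict_mm: int = 1,
                  expanded_mm: int = 3) -> list[SpacerMatch]:
    """Match array spacers against target contigs.

    Strict tier: full-spacer ungapped alignment of length
    >= ``min_align_len`` (i.e. > 24 bp) with <= ``strict_mm`` mismatches.
    For every (array, target) pair with at least one strict match, the
    array's spacers are rescanned against that target allowing up to
    ``expanded_mm`` mismatches; the additional hits form the expanded tier.
    Matches of an array against its own span on the same contig are
    suppressed (an array trivially contains its own spacers).
    """
    if not arrays:
        raise ValueError("no arrays given")
    matches: list[SpacerMatch] = []
    strict_pairs: set[tuple] = set()
    per_array: dict[tuple, list] = {}
    for a in arrays:
        key = (a.contig_id, a.start)
        per_array[key] = list(zip(a.spacer_ids(), [s for _, s in a.spacers]))
    index = _TargetIndex(targets)

    def _self_hit(a_key, target_id, pos, slen):
        cid, astart = a_key
        if cid != target_id:
            return False
        arr = next(x for x in arrays if (x.contig_id, x.start) == a_key)
        return pos >= arr.start - slen and pos < arr.end

    seen: set[tuple] = set()
    for a_key, spacers in per_array.items():
        for t in targets:
            for sid, sp in spacers:
                if len(sp) < min_align_len:
                    continue
                for pos, strand, mm in _scan_one(sp, t.id, index, strict_mm):
                    if _self_hit(a_key, t.id, pos, len(sp)):
                        continue
                    matches.append(SpacerMatch(sid, a_key, a_key[0], t.id, pos,
                                               strand, len(sp), mm, "strict"))
                    seen.add((sid, t.id, pos, strand))
                    strict_pairs.add((a_key, t.id))
    for a_key, target_id in sorted(strict_pairs):
        for sid, sp in per_array[a_key]:
            if len(sp) < min_align_len:
                continue
            for pos, strand, mm in _scan_one(sp, target_id, index, expanded_mm):
                if (sid, target_id, pos, strand) in seen:
                    continue
                if _self_hit(a_key, target_id, pos, len(sp)):
                    continue
                matches.append(SpacerMatch(sid, a_key, a_key[0], target_id, pos,
                                           strand, len(sp), mm, "expanded"))
                seen.add((sid, target_id, pos, strand))
    matches.sort(key=lambda m: (m.source_contig, m.target_contig,
                                m.spacer_id, m.target_start))
    return matches


# ---------------------------------------------------------------------------
# Repeat comparison (phage vs host array repeats)
# ---------------------------------------------------------------------------

def compare_repeats(repeat_a: str, repeat_b: str,
                    min_overlap_frac: float = 0.5) -> tuple[float, int, str]:
    """Best ungapped sliding alignment of two consensus repeats.

    Both orientations of ``repeat_b`` are tried; identity is computed over
    the overlapping columns, requiring an overlap of at least
    ``min_overlap_frac`` of the shorter repeat. Returns
    ``(identity, offset, orientation)`` with orientation "+" or "-".
    """
    a = repeat_a.upper()
    best = (0.0, 0, "+")
    min_ov = max(8, int(min_overlap_frac * min(len(repeat_a), len(repeat_b))))
    for orient, b in (("+", repeat_b.upper()), ("-", _seq.revcomp(repeat_b))):
        for off in range(-len(b) + min_ov, len(a) - min_ov + 1):
            lo_a, hi_a = max(0, off), min(len(a), off + len(b))
            if hi_a - lo_a < min_ov:
                continue
            seg_a = a[lo_a:hi_a]
            seg_b = b[lo_a - off: hi_a - off]
            ident = sum(x == y for x, y in zip(seg_a, seg_b)) / len(seg_a)
            if ident > best[0]:
                best = (ident, off, orient)
    return best


# ---------------------------------------------------------------------------
# Interaction network
# ---------------------------------------------------------------------------

def build_network(matches: list[SpacerMatch],
                  node_types: dict | None = None) -> list[InteractionEdge]:
    """Collapse spacer matches into directed interaction edges.

    One edge per (array-owner contig, target contig) pair, carrying strict
    and expanded match counts; solid if backed by >= 1 strict match,
    dashed if supported only by 2-3-mismatch hits. Self-targeting edges
    (owner == target) are reported with ``self_targeting=True``.
    ``node_types`` (contig -> "phage"/"bacteria"/...) is attached by the
    caller when exporting; it does not change the topology.
    """
    counts: dict[tuple, list] = {}
    for m in matches:
        key = (m.source_contig, m.target_contig)
        c = counts.setdefault(key, [0, 0])
        c[0 if m.tier == "strict" else 1] += 1
    edges = []
    for (src, dst), (ns, ne) in sorted(counts.items()):
        edges.append(InteractionEdge(
            source=src, target=dst, n_strict=ns, n_expanded=ne,
            style="solid" if ns >= 1 else "dashed",
            self_targeting=src == dst))
    return edges


def network_to_graphml(edges: list[InteractionEdge], node_types: dict,
                       path) -> None:
    """Write the interaction network as GraphML via networkx."""
    import networkx as nx

    g = nx.MultiDiGraph()
    for e in edges:
        for node in (e.source, e.target):
            if node not in g:
                g.add_node(node, node_type=node_types.get(node, "unknown"))
        g.add_edge(e.source, e.target, n_strict=e.n_strict,
                   n_expanded=e.n_expanded, style=e.style,
                   self_targeting=e.self_targeting)
    nx.write_graphml(g, path)
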