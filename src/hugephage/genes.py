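"""Minimal ORF calling under configurable genetic codes and inference of
stop-codon reassignment.

Huge phage genomes called under the standard bacterial code (translation
table 11) sometimes show anomalously low coding density because a stop
codon — most often TAG (amber) — has been reassigned to a sense codon.
This module provides a deliberately simple, fully specified ORF caller
(maximal ORFs on both strands, greedy overlap resolution) so that coding
density is a well-defined, reproducible statistic, plus the re-prediction
logic that flags low-density genomes and tests alternative codes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from Bio.Data import CodonTable

from . import _seq
from .records import ContigRecord, GeneCall

START_CODONS = ("ATG", "GTG", "TTG")

_ALL_CODONS = ["".join(c) for c in itertools.product("TCAG", repeat=3)]


def _table11_forward() -> dict[str, str]:
    tbl = CodonTable.unambiguous_dna_by_id[11]
    fwd = dict(tbl.forward_table)
    for c in tbl.stop_codons:
        fwd[c] = "*"
    return fwd


_CODE11 = _table11_forward()


@dataclass(frozen=True)
class GeneticCode:
    """A translation table defined as code 11 plus stop-codon reassignments.

    ``reassigned`` maps former stop codons to the amino acid they now
    encode ("X" if unknown). Remaining stop codons are code 11's stops
    minus the reassigned ones.
    """

    id: str
    reassigned: dict = field(default_factory=dict)

    @property
    def stop_codons(self) -> frozenset:
        stops = {"TAA", "TAG", "TGA"} - set(self.reassigned)
        if not stops:
            raise ValueError(f"genetic code {self.id} has no stop codon left")
        return frozenset(stops)

    def codon_map(self) -> dict[str, str]:
        m = dict(_CODE11)
        m.update(self.reassigned)
        return m

    def translate(self, cds: str) -> str:
        m = self.codon_map()
        aa = [m[cds[i : i + 3]] for i in range(0, len(cds) - len(cds) % 3, 3)]
        if aa and aa[-1] == "*":
            aa.pop()
        return "".join(aa)


#: Standard bacterial code.
CODE11 = GeneticCode("code11")
#: Amber (TAG) read through as glutamine, as seen in Lak-like phages.
TAG_RECODED = GeneticCode("TAG_recoded", {"TAG": "Q"})
#: Opal (TGA) read through as tryptophan.
TGA_RECODED = GeneticCode("TGA_recoded", {"TGA": "W"})
#: Ciliate-like code with a single stop codon (TGA); TAA/TAG -> Gln.
CODE6_LIKE = GeneticCode("code6_like", {"TAA": "Q", "TAG": "Q"})

GENETIC_CODES = {c.id: c for c in (CODE11, TAG_RECODED, TGA_RECODED, CODE6_LIKE)}


def _codon_id(codon: str) -> int:
    a = _seq.encode(codon)
    return int(a[0]) * 16 + int(a[1]) * 4 + int(a[2])


def _frame_orfs(ids: np.ndarray, stop_ids: set[int], start_ids: set[int],
                min_len_codons: int) -> list[tuple[int, int]]:
    """Maximal ORFs in one frame, as (start_codon_index, stop_codon_index).

    The stop codon at ``stop_codon_index`` belongs to the ORF. Segments
    running off the sequence end (no stop) are discarded: every reported
    ORF ends at a stop codon of the code.
    """
    stop_mask = np.isin(ids, list(stop_ids))
    start_mask = np.isin(ids, list(start_ids))
    stop_pos = np.flatnonzero(stop_mask)
    start_pos = np.flatnonzero(start_mask)
    if stop_pos.size == 0 or start_pos.size == 0:
        return []
    seg_begin = np.concatenate(([0], stop_pos[:-1] + 1))  # first codon after prev stop
    first_start = np.searchsorted(start_pos, seg_begin)
    orfs = []
    for k in range(stop_pos.size):
        if first_start[k] >= start_pos.size:
            continue
        s = start_pos[first_start[k]]
        e = stop_pos[k]
        if s > e:
            continue
        if e - s + 1 >= min_len_codons:
            orfs.append((int(s), int(e)))
    return orfs


def call_orfs(contig: ContigRecord, code: GeneticCode = CODE11,
              min_len_codons: int = 60, translate: bool = True) -> list[GeneCall]:
    """Call maximal ORFs on both strands under ``code``.

    An ORF starts at the first in-frame ATG/GTG/TTG after a stop codon and
    runs through the next stop codon (included in the coordinates).
    Overlapping calls (any strand) are resolved greedily by length, ties by
    leftmost start then by + strand.
    """
    seq = contig.seq
    arr = _seq.encode(seq)
    n = arr.size
    stop_ids = {_codon_id(c) for c in code.stop_codons}
    start_ids = {_codon_id(c) for c in START_CODONS}
    candidates: list[tuple[int, int, str]] = []  # (start, end, strand) forward axis
    for strand, a in (("+", arr), ("-", _seq.revcomp_arr(arr))):
        for frame in range(3):
            m = (n - frame) // 3
            if m < 1:
                continue
            trimmed = a[frame : frame + 3 * m]
            ids = (trimmed[0::3].astype(np.int64) * 16
                   + trimmed[1::3].astype(np.int64) * 4
                   + trimmed[2::3].astype(np.int64))
            for s_codon, e_codon in _frame_orfs(ids, stop_ids, start_ids, min_len_codons):
                lo = frame + 3 * s_codon
                hi = frame + 3 * (e_codon + 1)
                if strand == "+":
                    candidates.append((lo, hi, "+"))
                else:
                    candidates.append((n - hi, n - lo, "-"))
    # Greedy overlap resolution: longest first, then leftmost, then + strand.
    candidates.sort(key=lambda c: (-(c[1] - c[0]), c[0], 0 if c[2] == "+" else 1))
    chosen: list[tuple[int, int, str]] = []
    occupied = np.zeros(n, dtype=bool)
    for lo, hi, strand in candidates:
        if occupied[lo:hi].any():
            continue
        occupied[lo:hi] = True
        chosen.append((lo, hi, strand))
    chosen.sort()
    calls = []
    for i, (lo, hi, strand) in enumerate(chosen):
        cds = seq[lo:hi] if strand == "+" else _seq.revcomp(seq[lo:hi])
        calls.append(GeneCall(
            contig_id=contig.id,
            gene_id=f"{contig.id}_g{i + 1:05d}",
            start=lo, end=hi, strand=strand, code_id=code.id,
            translation=code.translate(cds) if translate else "",
        ))
    return calls


def coding_density(contig: ContigRecord, genes: list[GeneCall]) -> float:
    """Fraction of contig positions covered by at least one gene (union)."""
    n = len(contig.seq)
    if n == 0:
        return 0.0
    ivs = sorted((g.start, g.end) for g in genes)
    covered = 0
    cur_lo, cur_hi = None, None
    for lo, hi in ivs:
        if hi > n or lo < 0:
            raise ValueError(f"gene [{lo},{hi}) outside contig of length {n}")
        if cur_hi is None or lo > cur_hi:
            if cur_hi is not None:
                covered += cur_hi - cur_lo
            cur_lo, cur_hi = lo, hi
        else:
            cur_hi = max(cur_hi, hi)
    if cur_hi is not None:
        covered += cur_hi - cur_lo
    return covered / n


@dataclass
class CodeInferenceResult:
    chosen_code: str
    density_by_code: dict
    flagged: bool
    ruled_out: list  # (code_id, reason)
    genes_by_code: dict = field(default_factory=dict)


def _spans_k_reference_genes(gene: GeneCall, ref: list[GeneCall], k: int = 3) -> bool:
    n = sum(1 for r in ref if r.start >= gene.start and r.end <= gene.end)
    return n >= k


def _fusion_ruled_out(cand_genes: list[GeneCall], ref_genes: list[GeneCall],
                      p95_factor: float = 3.0, span_frac: float = 0.2) -> bool:
    """Heuristic rejection of codes that merge genes into implausible fusions.

    A candidate code is rejected if its 95th-percentile gene length exceeds
    ``p95_factor`` times that of the code-11 calls, or if more than
    ``span_frac`` of its genes each fully span >= 3 code-11 genes.
    """
    if not cand_genes or not ref_genes:
        return False
    p95_cand = float(np.percentile([g.end - g.start for g in cand_genes], 95))
    p95_ref = float(np.percentile([g.end - g.start for g in ref_genes], 95))
    if p95_ref > 0 and p95_cand > p95_factor * p95_ref:
        return True
    spanning = sum(1 for g in cand_genes if _spans_k_reference_genes(g, ref_genes))
    return spanning / len(cand_genes) > span_frac


def infer_genetic_code(contig: ContigRecord, flag_threshold: float = 0.78,
                       margin: float = 0.10, min_len_codons: int = 60,
                       candidates: tuple[str, ...] = ("TAG_recoded", "TGA_recoded"),
                       ) -> CodeInferenceResult:
    """Flag low-coding-density genomes and test alternative genetic codes.

    Genes are first called under code 11. If coding density falls below
    ``flag_threshold`` (default 0.78, the density regime at which standard
    code predictions are suspect), each candidate reassignment code is
    tried; a candidate wins only if its density exceeds the code-11 density
    by more than ``margin`` and it is not rejected by the gene-fusion check.
    """
    ref_genes = call_orfs(contig, CODE11, min_len_codons, translate=False)
    d11 = coding_density(contig, ref_genes)
    density = {"code11": d11}
    genes_by_code = {"code11": ref_genes}
    ruled_out: list[tuple[str, str]] = []
    flagged = d11 < flag_threshold
    chosen = "code11"
    if flagged:
        best = d11 + margin
        for cid in candidates:
            code = GENETIC_CODES[cid]
            g = call_orfs(contig, code, min_len_codons, translate=False)
            d = coding_density(contig, g)
            density[cid] = d
            genes_by_code[cid] = g
            if len(code.stop_codons) == 1 and _fusion_ruled_out(g, ref_genes):
                ruled_out.append((cid, "gene fusion"))
                continue
            if d > best:
                best = d
                chosen = cid
    return CodeInferenceResult(chosen, density, flagged, ruled_out, genes_by_code)
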