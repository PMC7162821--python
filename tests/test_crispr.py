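"""CRISPR array detection, spacer matching and the interaction network."""

import numpy as np
import pytest

import oracles
from hugephage import crispr
from hugephage.records import ContigRecord
from conftest import random_seq


def _plant_array(rng, seq_len, repeat_len=32, n_repeats=6, spacer_len=34,
                 pos=None):
    s = list(random_seq(rng, seq_len))
    repeat = random_seq(rng, repeat_len)
    spacers = [random_seq(rng, spacer_len) for _ in range(n_repeats - 1)]
    arr = repeat + "".join(sp + repeat for sp in spacers)
    if pos is None:
        pos = int(rng.integers(1_000, seq_len - len(arr) - 1_000))
    s[pos:pos + len(arr)] = list(arr)
    return "".join(s), repeat, spacers, pos, pos + len(arr)


class TestDetectArrays:
    def test_planted_array_recovered_exactly(self, rng):
        seq, repeat, spacers, start, end = _plant_array(rng, 100_000)
        arrays = crispr.detect_arrays(ContigRecord("c", seq))
        assert len(arrays) == 1
        a = arrays[0]
        assert abs(a.start - start) <= 2 and abs(a.end - end) <= 2
        assert a.n_repeats == 6
        assert repeat in a.consensus_repeat or a.consensus_repeat in repeat

    def test_min_repeats_boundary(self, rng):
        seq3, *_ = _plant_array(rng, 50_000, n_repeats=3)
        seq2, *_ = _plant_array(rng, 50_000, n_repeats=2)
        assert len(crispr.detect_arrays(ContigRecord("a", seq3))) == 1
        assert crispr.detect_arrays(ContigRecord("b", seq2)) == []

    def test_recovery_rate_across_repeat_and_spacer_ranges(self, rng):
        """>= 95% of planted arrays recovered over 200 seeded replicates
        spanning repeat lengths 21-45 bp and 4-10 spacers."""
        found = 0
        n_rep = 200
        for i in range(n_rep):
            rl = int(rng.integers(21, 46))
            ns = int(rng.integers(4, 11))
            sl = int(rng.integers(25, 45))
            seq, repeat, spacers, start, end = _plant_array(
                rng, 20_000, repeat_len=rl, n_repeats=ns + 1, spacer_len=sl)
            arrays = crispr.detect_arrays(ContigRecord("c", seq))
            if len(arrays) == 1 and abs(arrays[0].start - start) <= 2 \
                    and abs(arrays[0].end - end) <= 2 \
                    and arrays[0].n_repeats == ns + 1:
                found += 1
        assert found / n_rep >= 0.95

    def test_false_positive_rate_on_random_sequence(self, rng):
        """< 0.05 arrays per Mb on random sequence (measured over 4 Mb)."""
        n_arrays = 0
        for _ in range(20):
            n_arrays += len(crispr.detect_arrays(
                ContigRecord("r", random_seq(rng, 200_000))))
        assert n_arrays / 4.0 < 0.05

    def test_repeats_and_spacers_alternate(self, rng):
        seq, *_ = _plant_array(rng, 60_000)
        a = crispr.detect_arrays(ContigRecord("c", seq))[0]
        assert len(a.spacers) == a.n_repeats - 1
        for (rs, rseq), (ss, sseq) in zip(a.repeats, a.spacers):
            assert rs + len(rseq) == ss


class TestMatchSpacers:
    def _array_with_spacer(self, rng, spacer):
        """A contig carrying a real array whose first spacer is ``spacer``."""
        repeat = random_seq(rng, 32)
        others = [random_seq(rng, len(spacer)) for _ in range(3)]
        arr = repeat + "".join(sp + repeat for sp in [spacer] + others)
        seq = random_seq(rng, 5_000) + arr + random_seq(rng, 5_000)
        arrays = crispr.detect_arrays(ContigRecord("owner", seq))
        assert len(arrays) == 1
        return arrays

    @pytest.mark.parametrize("length,expected", [(24, 0), (25, 1)])
    def test_alignment_length_boundary(self, rng, length, expected):
        spacer = random_seq(rng, length)
        arrays = self._array_with_spacer(rng, spacer)
        target = ContigRecord("t", random_seq(rng, 3_000) + spacer
                              + random_seq(rng, 3_000))
        matches = crispr.match_spacers(arrays, [target])
        assert len([m for m in matches if m.target_contig == "t"]) == expected

    @pytest.mark.parametrize("mm,tier", [(0, "strict"), (1, "strict"), (2, None)])
    def test_mismatch_boundary_without_prior_strict_hit(self, rng, mm, tier):
        spacer = random_seq(rng, 34)
        mutated = list(spacer)
        for p in range(mm):
            mutated[3 * p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[3 * p]]
        arrays = self._array_with_spacer(rng, spacer)
        target = ContigRecord("t", random_seq(rng, 3_000) + "".join(mutated)
                              + random_seq(rng, 3_000))
        matches = [m for m in crispr.match_spacers(arrays, [target])
                   if m.target_contig == "t"]
        if tier is None:
            assert matches == []
        else:
            assert [m.tier for m in matches] == [tier]
            assert matches[0].mismatches == mm

    def test_expanded_tier_needs_strict_anchor_on_same_target(self, rng):
        spacer0 = random_seq(rng, 34)  # exact protospacer -> strict anchor
        spacer2 = random_seq(rng, 34)
        proto2 = list(spacer2)
        proto2[5] = {"A": "C", "C": "G", "G": "T", "T": "A"}[proto2[5]]
        proto2[15] = {"A": "C", "C": "G", "G": "T", "T": "A"}[proto2[15]]
        repeat = random_seq(rng, 32)
        arr = repeat + spacer0 + repeat + spacer2 + repeat \
            + random_seq(rng, 34) + repeat
        owner_seq = random_seq(rng, 4_000) + arr + random_seq(rng, 4_000)
        arrays = crispr.detect_arrays(ContigRecord("owner", owner_seq))
        with_anchor = ContigRecord("t1", random_seq(rng, 2_000) + spacer0
                                   + random_seq(rng, 2_000) + "".join(proto2)
                                   + random_seq(rng, 2_000))
        without_anchor = ContigRecord("t2", random_seq(rng, 2_000)
                                      + "".join(proto2) + random_seq(rng, 2_000))
        matches = crispr.match_spacers(arrays, [with_anchor, without_anchor])
        t1 = [(m.tier, m.mismatches) for m in matches if m.target_contig == "t1"]
        t2 = [m for m in matches if m.target_contig == "t2"]
        assert sorted(t1) == [("expanded", 2), ("strict", 0)]
        assert t2 == []  # 2-mismatch hit alone is never retained

    def test_equals_brute_force_hamming_scan(self, rng):
        for _ in range(25):
            target = random_seq(rng, 4_000)
            spacer = random_seq(rng, int(rng.integers(25, 40)))
            # plant a mutated copy half the time
            if rng.random() < 0.5:
                mutated = list(spacer)
                for p in rng.choice(len(spacer), size=int(rng.integers(0, 4)),
                                    replace=False):
                    mutated[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[p]]
                ins = int(rng.integers(0, len(target) - len(spacer)))
                target = target[:ins] + "".join(mutated) + \
                    target[ins + len(spacer):]
            for max_mm in (1, 3):
                got = crispr.scan_spacer(spacer, ContigRecord("t", target), max_mm)
                assert got == oracles.hamming_occurrences(spacer, target, max_mm)

    def test_no_arrays_raises(self):
        with pytest.raises(ValueError):
            crispr.match_spacers([], [])


class TestCompareRepeats:
    def test_identical_repeats(self, rng):
        r = random_seq(rng, 32)
        ident, off, orient = crispr.compare_repeats(r, r)
        assert ident == 1.0 and off == 0 and orient == "+"

    def test_reverse_complement_identical(self, rng):
        r = random_seq(rng, 32)
        ident, off, orient = crispr.compare_repeats(r, oracles.revcomp(r))
        assert ident == 1.0 and orient == "-"

    def test_unrelated_repeats_near_background(self, rng):
        worst = 0.0
        for _ in range(20):
            ident, _, _ = crispr.compare_repeats(random_seq(rng, 30),
                                                 random_seq(rng, 30))
            worst = max(worst, ident)
        assert worst <= 0.6


class TestNetwork:
    def _m(self, sid, src, dst, mm, tier):
        return crispr.SpacerMatch(sid, (src, 0), src, dst, 100, "+", 34, mm, tier)

    def test_strict_match_gives_solid_edge(self):
        edges = crispr.build_network([self._m("s1", "phageA", "phageB", 0,
                                              "strict")])
        assert len(edges) == 1
        assert edges[0].style == "solid" and edges[0].n_strict == 1

    def test_expanded_only_gives_dashed_edge(self):
        edges = crispr.build_network([
            self._m("s1", "phageA", "phageB", 2, "expanded"),
            self._m("s2", "phageA", "phageB", 3, "expanded")])
        assert [e.style for e in edges] == ["dashed"]
        assert edges[0].n_expanded == 2

    def test_no_matches_empty_network(self):
        assert crispr.build_network([]) == []

    def test_self_targeting_flagged(self):
        edges = crispr.build_network([self._m("s1", "phageA", "phageA", 0,
                                              "strict")])
        assert edges[0].self_targeting

    def test_edge_counts_conserve_matches(self, community):
        arrays = []
        for c in community["contigs"]:
            arrays.extend(crispr.detect_arrays(c))
        matches = crispr.match_spacers(arrays, community["contigs"])
        edges = crispr.build_network(matches)
        assert sum(e.n_strict + e.n_expanded for e in edges) == len(matches)
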