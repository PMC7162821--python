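"""Assembly QC: circularization, repeats, concatemer flag, GC skew."""

import numpy as np
import pytest

import oracles
from hugephage import qc
from hugephage.records import ContigRecord, GeneCall
from hugephage.simulate import CommunitySpec, GenomeSpec, generate_genome
from conftest import random_seq


class TestCircularity:
    def test_random_sequence_has_no_overlap(self, rng):
        c = ContigRecord("r", random_seq(rng, 200_000))
        assert qc.detect_circularity(c).overlap is None

    def test_planted_overlap_recovered_and_flagged_complete(self, rng):
        s = random_seq(rng, 50_000)
        c = ContigRecord("c", s + s[:120])
        call = qc.detect_circularity(c)
        assert call.overlap == 120
        assert call.potentially_complete

    def test_short_contig_warns(self, rng):
        call = qc.detect_circularity(ContigRecord("s", random_seq(rng, 60)))
        assert call.overlap is None
        assert call.warning is not None

    def test_equals_brute_force_on_random_instances(self, rng):
        for _ in range(30):
            n = int(rng.integers(2_000, 20_000))
            s = random_seq(rng, n)
            if rng.random() < 0.7:  # plant an overlap most of the time
                k = int(rng.integers(50, 2_000))
                s = s[:-k] + s[:k]
            got = qc.detect_circularity(ContigRecord("x", s),
                                        min_overlap=50, max_overlap=5_000)
            exp = oracles.best_end_overlap(s, 50, 5_000)
            assert got.overlap == exp


class TestLongRepeats:
    def test_tandem_dimer_flagged_with_exact_unit_length(self, rng):
        unit = random_seq(rng, 250_000)
        c = ContigRecord("dimer", unit * 2)
        hits = qc.detect_long_direct_repeats(c)
        assert any(h.length >= 250_000 for h in hits)
        call = qc.flag_concatemer(c, hits)
        assert call.is_artifact
        assert call.corrected_length == 250_000

    def test_trimer_corrected_to_unit(self, rng):
        unit = random_seq(rng, 80_000)
        call = qc.flag_concatemer(ContigRecord("tri", unit * 3), [])
        assert call.is_artifact and call.corrected_length == 80_000

    def test_nontandem_repeat_needs_manual_review(self, rng):
        s = list(random_seq(rng, 100_000))
        s[60_000:66_000] = s[10_000:16_000]
        c = ContigRecord("two_loci", "".join(s))
        hits = qc.detect_long_direct_repeats(c)
        # the maximal repeat covers the planted 6 kb copy (chance flanking
        # matches may extend it by a base or two)
        assert len(hits) == 1
        h = hits[0]
        assert h.start1 <= 10_000 and h.start1 + h.length >= 16_000
        assert h.start2 <= 60_000 and 6_000 <= h.length <= 6_010
        call = qc.flag_concatemer(c, hits)
        assert not call.is_artifact
        assert call.needs_review

    @pytest.mark.parametrize("length,reported", [(4_999, False), (5_001, True)])
    def test_default_threshold_boundary(self, rng, length, reported):
        s = list(random_seq(rng, 60_000))
        s[40_000:40_000 + length] = s[2_000:2_000 + length]
        hits = qc.detect_long_direct_repeats(ContigRecord("b", "".join(s)))
        assert any(h.length >= length for h in hits) == reported

    def test_min_len_floor(self, rng):
        with pytest.raises(ValueError):
            qc.detect_long_direct_repeats(ContigRecord("x", random_seq(rng, 5_000)),
                                          min_len=500)


class TestShortRepeats:
    def test_planted_forty_bp_duplicate(self, rng):
        s = list(random_seq(rng, 30_000))
        s[20_000:20_040] = s[5_000:5_040]
        hits = qc.tabulate_short_repeats(ContigRecord("p", "".join(s)))
        direct = [h for h in hits if h.kind == "direct"]
        assert len(direct) == 1
        h = direct[0]
        assert h.start1 <= 5_000 and h.start1 + h.length >= 5_040
        assert 40 <= h.length <= 44

    def test_25bp_duplicate_absent(self, rng):
        s = list(random_seq(rng, 30_000))
        s[20_000:20_025] = s[5_000:5_025]
        hits = qc.tabulate_short_repeats(ContigRecord("p", "".join(s)))
        # a planted repeat of exactly 25 bp must not be reported (rule is > 25)
        assert all(h.length >= 26 for h in hits)
        assert not any(h.start1 == 5_000 and h.length == 25 for h in hits)

    def test_palindrome_reported_as_inverted(self, rng):
        s = list(random_seq(rng, 10_000))
        s[7_000:7_030] = list(oracles.revcomp("".join(s[3_000:3_030])))
        hits = qc.tabulate_short_repeats(ContigRecord("p", "".join(s)))
        inv = [h for h in hits if h.kind == "inverted"]
        assert any(h.start1 <= 3_000 and h.start1 + h.length >= 3_030
                   and h.start2 <= 7_000 and h.start2 + h.length >= 7_030
                   for h in inv)

    def test_equals_quadratic_brute_force(self, rng):
        for _ in range(10):
            n = int(rng.integers(2_000, 6_000))
            s = list(random_seq(rng, n))
            L = int(rng.integers(26, 60))
            p1 = int(rng.integers(0, n - 3 * L))
            p2 = int(rng.integers(p1 + L, n - L))
            s[p2:p2 + L] = s[p1:p1 + L]
            q1 = int(rng.integers(0, n - 3 * L))
            q2 = int(rng.integers(q1 + L, n - L))
            s[q2:q2 + L] = list(oracles.revcomp("".join(s[q1:q1 + L])))
            seq = "".join(s)
            got = {(h.start1, h.start2, h.length, h.kind)
                   for h in qc.tabulate_short_repeats(ContigRecord("x", seq))}
            exp = {(a, b, l, "direct") for a, b, l in oracles.direct_repeats(seq, 26)} \
                | {(a, b, l, "inverted") for a, b, l in oracles.inverted_repeats(seq, 26)}
            assert got == exp


class TestGcSkew:
    def test_cumulative_telescopes_when_step_equals_window(self, rng):
        seq = random_seq(rng, 50_000)
        prof = qc.gc_skew(ContigRecord("t", seq), window=1_000, step=1_000)
        profiled = seq[:50 * 1_000]
        assert prof.cumulative[-1] == profiled.count("G") - profiled.count("C")
        assert len(prof.positions) == len(prof.skew)

    def test_zero_gc_window_skew_is_zero(self):
        prof = qc.gc_skew(ContigRecord("at", "AT" * 500), window=100, step=100)
        assert np.all(prof.skew == 0.0)

    def test_random_sequence_mode_none(self, rng):
        prof = qc.gc_skew(ContigRecord("r", random_seq(rng, 300_000)))
        assert qc.classify_replication_mode(prof) == "none"

    def test_too_few_windows_warns(self, rng):
        prof = qc.gc_skew(ContigRecord("tiny", random_seq(rng, 3_000)))
        assert qc.classify_replication_mode(prof) == "none"
        assert prof.warning is not None

    def test_bidirectional_recovered_with_breakpoints(self):
        contig, _, truth = generate_genome(GenomeSpec(
            name="bi", length=400_000, skew_mode="bidirectional"), seed=8)
        prof = qc.gc_skew(contig)
        assert qc.classify_replication_mode(prof) == "bidirectional"
        assert len(prof.breakpoints) == 2
        for got, exp in zip(prof.breakpoints, truth.skew_breakpoints):
            assert abs(got - exp) <= 5_000
        # origin is the falling-to-rising inflection
        assert abs(prof.origin - truth.skew_breakpoints[0]) <= 5_000

    def test_unidirectional_recovered(self):
        contig, _, _ = generate_genome(GenomeSpec(
            name="uni", length=300_000, skew_mode="unidirectional"), seed=8)
        prof = qc.gc_skew(contig)
        assert qc.classify_replication_mode(prof) == "unidirectional"


class TestReorientation:
    def _circular_genome(self, seed=13):
        contig, _, truth = generate_genome(GenomeSpec(
            name="c", length=300_000, skew_mode="bidirectional",
            terminal_overlap_bp=120), seed=seed)
        return contig, truth

    def test_rotation_preserves_length_and_is_invertible(self):
        contig, truth = self._circular_genome()
        from hugephage.genes import call_orfs

        genes = call_orfs(contig, translate=False)
        prof = qc.gc_skew(contig)
        qc.classify_replication_mode(prof)
        res = qc.reorient_to_origin(contig, prof, genes, overlap=120)
        trimmed = contig.seq[:-120]
        assert len(res.contig.seq) == len(trimmed)
        restored = res.contig.seq[-res.offset:] + res.contig.seq[:-res.offset] \
            if res.offset else res.contig.seq
        assert restored == trimmed

    def test_new_start_is_intergenic_near_origin(self):
        contig, truth = self._circular_genome()
        from hugephage.genes import call_orfs

        genes = call_orfs(contig, translate=False)
        prof = qc.gc_skew(contig)
        qc.classify_replication_mode(prof)
        res = qc.reorient_to_origin(contig, prof, genes, overlap=120)
        assert abs(res.offset - prof.origin) <= 5_000
        # offset falls in a gap between genes
        for g in genes:
            if g.end <= len(contig.seq) - 120:
                assert not (g.start < res.offset < g.end)

    def test_mode_none_returns_unrotated_with_warning(self, rng):
        s = random_seq(rng, 50_000)
        contig = ContigRecord("n", s + s[:100])
        prof = qc.gc_skew(contig)
        qc.classify_replication_mode(prof)
        res = qc.reorient_to_origin(contig, prof, [], overlap=100)
        assert res.warning is not None
        assert res.contig.seq == s

    def test_noncircular_input_raises(self, rng):
        contig = ContigRecord("lin", random_seq(rng, 50_000))
        prof = qc.gc_skew(contig)
        with pytest.raises(ValueError):
            qc.reorient_to_origin(contig, prof, [], overlap=0)
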