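"""Taxonomy voting, marker detection and the element-type rule engine."""

import itertools

import numpy as np
import pandas as pd
import pytest

from hugephage import classify
from hugephage.records import ContigRecord
from conftest import random_seq


def _hits(rows):
    base = {"contig_id": "c1", "gene_id": None, "domain": None, "phylum": None,
            "class": None, "order": None, "family": None, "genus": None,
            "keyword": "hypothetical protein", "bitscore": 100.0}
    out = []
    for i, r in enumerate(rows):
        d = dict(base)
        d.update(r)
        if d["gene_id"] is None:
            d["gene_id"] = f"g{i:03d}"
        out.append(d)
    return pd.DataFrame(out, columns=list(base) + ["start", "end"])


class TestVoteTaxonomy:
    def test_strict_majority_wins(self):
        hits = _hits([{"phylum": "Firmicutes"}] * 6
                     + [{"phylum": "Proteobacteria"}] * 4)
        votes = classify.vote_taxonomy(hits, "c1")
        assert votes["phylum"].winner == "Firmicutes"
        assert votes["phylum"].tallies == {"Firmicutes": 6, "Proteobacteria": 4}

    def test_exactly_half_is_no_winner(self):
        hits = _hits([{"phylum": "Firmicutes"}] * 5
                     + [{"phylum": "Proteobacteria"}] * 5)
        assert classify.vote_taxonomy(hits, "c1")["phylum"].winner is None

    def test_empty_table_all_ranks_winnerless(self):
        hits = _hits([]).iloc[0:0]
        votes = classify.vote_taxonomy(hits, "c1")
        assert all(v.winner is None for v in votes.values())

    def test_abstaining_genes_excluded_from_denominator(self):
        # 3 of 10 genes vote, 2 for Firmicutes: 2/3 > 50% of voters
        hits = _hits([{"phylum": "Firmicutes"}] * 2
                     + [{"phylum": "Bacteroidetes"}]
                     + [{"phylum": None}] * 7)
        assert classify.vote_taxonomy(hits, "c1")["phylum"].winner == "Firmicutes"


class TestMarkers:
    def test_terminase_keyword_detected(self):
        hits = _hits([{"keyword": "Large Terminase Subunit"}])
        assert "terminase" in classify.find_phage_markers(hits)

    def test_plasmid_keywords_detected(self):
        hits = _hits([{"keyword": "ParA partition protein"},
                      {"keyword": "conjugative transfer protein TraG"}])
        assert classify.find_plasmid_genes(hits) == {"partitioning", "conjugation"}

    def test_all_hypothetical_fraction_one(self):
        hits = _hits([{"keyword": "hypothetical protein"}] * 5)
        assert classify.hypothetical_fraction(hits, 5) == 1.0

    def test_absent_genes_count_as_hypothetical(self):
        hits = _hits([{"keyword": "DNA polymerase"}])
        assert classify.hypothetical_fraction(hits, 4) == 0.75

    def test_empty_gene_set_raises(self):
        with pytest.raises(ValueError):
            classify.hypothetical_fraction(_hits([]), 0)


class TestProphageTransition:
    def test_planted_prophage_boundaries_recovered(self, community):
        truth = community["truth"].contigs["phage_05"]
        contig = community["by_id"]["phage_05"]
        bounds = classify.detect_prophage_transition(contig,
                                                     community["annotations"])
        assert len(bounds) == 2
        for got, exp in zip(bounds, truth.prophage_bounds):
            assert abs(got - exp) <= 5_000

    def test_pure_phage_contig_has_no_boundary(self, community):
        contig = community["by_id"]["phage_01"]
        assert classify.detect_prophage_transition(
            contig, community["annotations"]) == []

    def test_host_contig_has_no_boundary(self, community):
        contig = community["by_id"]["host_01"]
        assert classify.detect_prophage_transition(
            contig, community["annotations"]) == []

    def test_short_flank_not_called(self, rng):
        # 10 kb bacterial flank is below the 20 kb window
        n_flank, n_core = 10, 100
        rows = []
        pos = 0
        for i in range(n_flank + n_core):
            conf = i < n_flank
            rows.append({"gene_id": f"g{i:03d}", "start": pos, "end": pos + 950,
                         "domain": "Bacteria" if conf else "Viruses",
                         "keyword": "DNA polymerase" if conf else
                         "hypothetical protein",
                         "bitscore": 150.0 if conf else 50.0})
            pos += 1_000
        contig = ContigRecord("c1", random_seq(rng, pos))
        assert classify.detect_prophage_transition(contig, _hits(rows)) == []


def _votes(domain_winner):
    return {r: classify.TaxonomyVote(r, {}, domain_winner if r == "domain" else None)
            for r in ("domain", "phylum", "class", "order", "family", "genus")}


class TestClassifyElement:
    @pytest.fixture()
    def contig(self, rng):
        return ContigRecord("c1", random_seq(rng, 250_000))

    def test_markers_make_phage(self, contig):
        res = classify.classify_element(contig, _votes(None),
                                        {"terminase", "capsid"}, 0.7, set(),
                                        crispr_present=False)
        assert res.element_type == "phage"

    def test_plasmid_genes_without_markers_make_plasmid_like(self, contig):
        res = classify.classify_element(contig, _votes("Bacteria"), set(), 0.4,
                                        {"partitioning", "conjugation"},
                                        crispr_present=False)
        assert res.element_type == "plasmid_like"

    def test_prophage_rule_fires_first(self, contig):
        res = classify.classify_element(contig, _votes(None), {"capsid"}, 0.7,
                                        set(), crispr_present=False,
                                        prophage_bounds=[40_000])
        assert res.element_type == "prophage_containing"

    def test_markerless_high_hypothetical_no_domain_winner_is_phage(self, contig):
        res = classify.classify_element(contig, _votes(None), set(), 0.65, set(),
                                        crispr_present=False)
        assert res.element_type == "phage"

    def test_domain_winner_blocks_hypothetical_route(self, contig):
        res = classify.classify_element(contig, _votes("Bacteria"), set(), 0.65,
                                        set(), crispr_present=False)
        assert res.element_type == "unknown"

    def test_length_exception_only_with_crispr(self, rng):
        short = ContigRecord("s", random_seq(rng, 180_000))
        rejected = classify.classify_element(short, _votes(None), {"capsid"},
                                             0.7, set(), crispr_present=False)
        assert rejected.rejected and not rejected.length_exception
        kept = classify.classify_element(short, _votes(None), {"capsid"}, 0.7,
                                         set(), crispr_present=True)
        assert not kept.rejected and kept.length_exception
        assert kept.element_type == "phage"

    def test_decision_table_exhaustive(self, contig):
        """Every combination of rule inputs lands in exactly the element
        type the ordered rules dictate."""
        for prophage, plasmid, markers, dom_win, high_hypo in \
                itertools.product([False, True], repeat=5):
            res = classify.classify_element(
                contig, _votes("Bacteria" if dom_win else None),
                {"capsid"} if markers else set(),
                0.8 if high_hypo else 0.2,
                {"partitioning"} if plasmid else set(),
                crispr_present=False,
                prophage_bounds=[40_000] if prophage else None)
            if prophage:
                expected = "prophage_containing"
            elif plasmid and not markers:
                expected = "plasmid_like"
            elif markers or (not dom_win and high_hypo):
                expected = "phage"
            else:
                expected = "unknown"
            assert res.element_type == expected
            assert res.rule_trace  # every decision is traceable

    def test_rule_engine_is_pure(self, contig):
        args = (contig, _votes(None), {"capsid"}, 0.7, set())
        r1 = classify.classify_element(*args, crispr_present=False)
        r2 = classify.classify_element(*args, crispr_present=False)
        assert r1 == r2


class TestCommunityRecovery:
    def test_element_types_recovered_exactly(self, community):
        ann = community["annotations"]
        from hugephage import crispr as crispr_mod
        from hugephage import genes as genes_mod

        for c in community["contigs"]:
            t = community["truth"].contigs[c.id]
            votes = classify.vote_taxonomy(ann, c.id)
            markers = classify.find_phage_markers(ann, c.id)
            plasmid = classify.find_plasmid_genes(ann, c.id)
            n_genes = len(t.genes)
            hypo = classify.hypothetical_fraction(ann, n_genes, c.id)
            bounds = classify.detect_prophage_transition(c, ann)
            arrays = crispr_mod.detect_arrays(c)
            res = classify.classify_element(c, votes, markers, hypo, plasmid,
                                            crispr_present=bool(arrays),
                                            prophage_bounds=bounds)
            expected = t.element_type if t.kind != "host" else "unknown"
            assert res.element_type == expected, c.id
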