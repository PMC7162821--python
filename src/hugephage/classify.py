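"""Element-type classification of large contigs.

Candidate mobile elements are classified as phage, plasmid-like,
prophage-containing or unknown from their gene-annotation inventories:

1. a taxonomy voting scheme (strict majority per rank over genes' best
   database hits; genes without a hit abstain);
2. phage marker genes (capsid, tail, terminase, spike, holin, portal,
   baseplate) matched case-insensitively against a keyword lexicon;
3. plasmid partitioning / conjugative-transfer genes;
4. a prophage test looking for a transition into flanking bacterial
   sequence with a high fraction of confident functional predictions.

Contigs under the 200 kb huge-phage size floor are rejected unless they
carry a CRISPR array (the same exception the source survey applied).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .records import RANKS, ContigRecord

MIN_ELEMENT_LENGTH = 200_000


@dataclass
class TaxonomyVote:
    rank: str
    tallies: dict
    winner: str | None  # present iff > 50% of voting genes


@dataclass
class ClassificationResult:
    contig_id: str
    element_type: str  # phage | plasmid_like | prophage_containing | unknown
    hypothetical_fraction: float
    markers_found: set
    rule_trace: list
    length_exception: bool = False
    rejected: bool = False
    prophage_bounds: tuple | None = None


def _load_lexicon() -> dict:
    """Marker lexicon: keyword-class -> trigger substrings (editable TSV)."""
    lex: dict[str, list[str]] = {}
    text = resources.files("hugephage.data").joinpath("markers.tsv").read_text()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        cls, category, trigger = line.split("\t")
        lex.setdefault(category, []).append((cls, trigger.lower()))
    return lex


_LEXICON = None


def marker_lexicon() -> dict:
    global _LEXICON
    if _LEXICON is None:
        _LEXICON = _load_lexicon()
    return _LEXICON


def vote_taxonomy(hits: pd.DataFrame, contig_id: str) -> dict:
    """Per-rank taxonomy vote over a contig's gene hits.

    A rank's winner is the taxon with strictly more than 50% of that
    rank's voting genes (genes whose hit carries a taxon at the rank);
    genes without a hit, or without a call at the rank, abstain.
    """
    sub = hits[hits["contig_id"] == contig_id]
    votes = {}
    for rank in RANKS:
        if rank in sub.columns:
            col = sub[rank].dropna()
        else:
            col = pd.Series([], dtype=object)
        tallies = col.value_counts().to_dict()
        total = int(col.size)
        winner = None
        if total:
            top, cnt = max(sorted(tallies.items()), key=lambda kv: kv[1])
            if cnt > total / 2:
                winner = top
        votes[rank] = TaxonomyVote(rank, tallies, winner)
    return votes


def find_phage_markers(hits: pd.DataFrame, contig_id: str | None = None) -> set:
    """Phage-specific gene classes present among the annotations."""
    sub = hits if contig_id is None else hits[hits["contig_id"] == contig_id]
    found = set()
    kw = sub["keyword"].dropna().str.lower()
    for cls, trigger in marker_lexicon().get("phage", []):
        if kw.str.contains(trigger, regex=False).any():
            found.add(cls)
    return found


def find_plasmid_genes(hits: pd.DataFrame, contig_id: str | None = None) -> set:
    """Plasmid partitioning / conjugative-transfer gene classes present."""
    sub = hits if contig_id is None else hits[hits["contig_id"] == contig_id]
    found = set()
    kw = sub["keyword"].dropna().str.lower()
    for cls, trigger in marker_lexicon().get("plasmid", []):
        if kw.str.contains(trigger, regex=False).any():
            found.add(cls)
    return found


def hypothetical_fraction(hits: pd.DataFrame, n_genes: int,
                          contig_id: str | None = None) -> float:
    """Fraction of genes without a functional keyword.

    Genes absent from the hit table count as hypothetical; ``n_genes``
    is the total number of genes on the contig.
    """
    if n_genes <= 0:
        raise ValueError("hypothetical_fraction undefined for an empty gene set")
    sub = hits if contig_id is None else hits[hits["contig_id"] == contig_id]
    functional = sub[
        sub["keyword"].notna()
        & (sub["keyword"].str.lower() != "hypothetical protein")
    ]["gene_id"].nunique()
    return max(0.0, (n_genes - functional) / n_genes)


def _confident_bacterial(row, min_bitscore: float) -> bool:
    kw = row["keyword"]
    return (isinstance(kw, str)
            and kw.lower() != "hypothetical protein"
            and row["bitscore"] >= min_bitscore
            and row.get("domain") == "Bacteria")


def detect_prophage_transition(contig: ContigRecord, hits: pd.DataFrame,
                               window: int = 20_000,
                               confident_frac: float = 0.7,
                               min_bitscore: float = 60.0,
                               interior_max_cov: float = 0.4,
                               flank_min_cov: float = 0.5) -> list:
    """Find transitions from a phage-like interior into bacterial flanks.

    A boundary is called where a terminal region at least ``window`` bp
    long has >= ``confident_frac`` of its (hit-bearing) genes with
    confident bacterial functional predictions (non-hypothetical keyword,
    bitscore >= ``min_bitscore``, bacterial domain) and at least
    ``flank_min_cov`` of its bases covered by such genes, while the
    region just inside the boundary (two windows deep) has confident-gene
    coverage of at most ``interior_max_cov``. Among qualifying
    boundaries, the one with the largest flank-vs-interior contrast is
    reported for each end. Returns 0, 1 or 2 positions (bp).
    """
    sub = hits[hits["contig_id"] == contig.id]
    if sub.empty or "start" not in sub.columns:
        return []
    genes = sub.sort_values("start")[["start", "end", "keyword", "bitscore", "domain"]]
    conf = genes.apply(_confident_bacterial, axis=1, min_bitscore=min_bitscore).to_numpy()
    starts = genes["start"].to_numpy()
    ends = genes["end"].to_numpy()
    n = len(genes)
    length = len(contig.seq)
    conf_ivs = [(s, e) for s, e, c in zip(starts, ends, conf) if c]

    def cov(lo: int, hi: int) -> float:
        if hi <= lo:
            return 0.0
        covered = sum(max(0, min(e, hi) - max(s, lo)) for s, e in conf_ivs)
        return covered / (hi - lo)

    bounds = []
    best = (None, -np.inf)
    for i in range(1, n):
        b = int(ends[i - 1])
        if b < window or b + 2 * window > length:
            continue
        flank_frac = conf[:i].mean()
        flank_cov = cov(0, b)
        interior_cov = cov(b, b + 2 * window)
        if (flank_frac >= confident_frac and flank_cov >= flank_min_cov
                and interior_cov <= interior_max_cov):
            score = flank_frac + flank_cov - interior_cov
            if score > best[1]:
                best = (b, score)
    if best[0] is not None:
        bounds.append(best[0])
    best = (None, -np.inf)
    for i in range(n - 1, 0, -1):
        b = int(starts[i])
        if length - b < window or b - 2 * window < 0:
            continue
        flank_frac = conf[i:].mean()
        flank_cov = cov(b, length)
        interior_cov = cov(b - 2 * window, b)
        if (flank_frac >= confident_frac and flank_cov >= flank_min_cov
                and interior_cov <= interior_max_cov):
            score = flank_frac + flank_cov - interior_cov
            if score > best[1]:
                best = (b, score)
    if best[0] is not None:
        bounds.append(best[0])
    return sorted(bounds)


def classify_element(contig: ContigRecord, votes: dict, markers: set,
                     hypo_fraction: float, plasmid_hits: set,
                     crispr_present: bool,
                     prophage_bounds: list | None = None,
                     high_hypo_threshold: float = 0.6,
                     placement_override: bool = False) -> ClassificationResult:
    """Apply the element-type decision rules in order.

    1. a prophage transition makes the element prophage_containing;
    2. plasmid partitioning/conjugation genes with no phage markers make
       it plasmid-like;
    3. phage markers, a placement override, or (no domain-level taxonomy
       winner and a high hypothetical fraction) make it a phage;
    4. anything else is unknown.

    Contigs shorter than 200 kb are rejected unless they carry a CRISPR
    array (``length_exception``).
    """
    trace = []
    rejected = False
    length_exception = False
    if len(contig.seq) < MIN_ELEMENT_LENGTH:
        if crispr_present:
            length_exception = True
            trace.append(f"<{MIN_ELEMENT_LENGTH} bp but CRISPR present: retained")
        else:
            rejected = True
            trace.append(f"<{MIN_ELEMENT_LENGTH} bp and no CRISPR: rejected")
    domain_winner = votes.get("domain") and votes["domain"].winner
    if prophage_bounds:
        etype = "prophage_containing"
        trace.append(f"prophage transition at {prophage_bounds}")
    elif plasmid_hits and not markers:
        etype = "plasmid_like"
        trace.append(f"plasmid genes {sorted(plasmid_hits)} and no phage markers")
    elif markers or placement_override or (
            domain_winner is None and hypo_fraction >= high_hypo_threshold):
        etype = "phage"
        if markers:
            trace.append(f"phage markers {sorted(markers)}")
        elif placement_override:
            trace.append("placement override")
        else:
            trace.append(
                f"no domain winner and hypothetical fraction "
                f"{hypo_fraction:.2f} >= {high_hypo_threshold}")
    else:
        etype = "unknown"
        trace.append("no rule fired")
    return ClassificationResult(
        contig_id=contig.id, element_type=etype,
        hypothetical_fraction=hypo_fraction, markers_found=set(markers),
        rule_trace=trace, length_exception=length_exception,
        rejected=rejected,
        prophage_bounds=tuple(prophage_bounds) if prophage_bounds else None)
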