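"""Core record types shared by every analysis stage."""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class ContigRecord:
    """A nucleotide sequence with an id and provenance.

    ``source`` is ``"synthetic"`` for generator output and ``"user"`` for
    sequences read from FASTA input.
    """

    id: str
    seq: str
    source: str = "user"

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class GeneCall:
    """A predicted ORF.

    Coordinates are 0-based half-open on the forward axis and include the
    stop codon. ``strand`` is ``"+"`` or ``"-"``; for minus-strand genes the
    coordinates still refer to the forward strand.
    """

    contig_id: str
    gene_id: str
    start: int
    end: int
    strand: str
    code_id: str = "code11"
    translation: str = ""

    @property
    def n_codons(self) -> int:
        return (self.end - self.start) // 3

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.start < 0 or self.end <= self.start:
            raise ValueError(f"bad gene coordinates [{self.start}, {self.end})")


# Taxonomic ranks used throughout, in descending order.
RANKS = ("domain", "phylum", "class", "order", "family", "genus")


@dataclass
class AnnotationHit:
    """Best database match of one gene: lineage + functional keyword."""

    contig_id: str
    gene_id: str
    lineage: dict = field(default_factory=dict)  # rank -> taxon (missing = no call)
    keyword: str = "hypothetical protein"
    bitscore: float = 0.0
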