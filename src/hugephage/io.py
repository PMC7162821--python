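"""Readers and writers for the toolkit's external formats.

FASTA goes through Biopython; tables are pandas TSV; gene calls and
CRISPR arrays are exported as GFF3 (1-based inclusive coordinates, per
the format; internal coordinates are 0-based half-open).
"""

from __future__ import annotations

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .records import ContigRecord, GeneCall


def read_fasta(path) -> list[ContigRecord]:
    return [ContigRecord(r.id, str(r.seq).upper(), source="user")
            for r in SeqIO.parse(str(path), "fasta")]


def write_fasta(contigs: list[ContigRecord], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for c in contigs:
            fh.write(f">{c.id}\n")
            for i in range(0, len(c.seq), width):
                fh.write(c.seq[i: i + width] + "\n")


def read_annotations(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"contig_id": str, "gene_id": str})


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def genes_to_gff3(genes: list[GeneCall], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id};genetic_code={g.code_id}"
            fh.write(f"{g.contig_id}\thugephage\tCDS\t{g.start + 1}\t{g.end}\t.\t"
                     f"{g.strand}\t0\t{attrs}\n")


def proteins_to_fasta(genes: list[GeneCall], path) -> None:
    records = [SeqRecord(Seq(g.translation), id=g.gene_id, description="")
               for g in genes if g.translation]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def arrays_to_gff3(arrays, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for a in arrays:
            aid = f"{a.contig_id}_{a.start}"
            fh.write(f"{a.contig_id}\thugephage\trepeat_region\t{a.start + 1}\t"
                     f"{a.end}\t.\t.\t.\tID={aid};n_repeats={a.n_repeats};"
                     f"consensus={a.consensus_repeat}\n")
            for i, (s, seq) in enumerate(a.spacers):
                fh.write(f"{a.contig_id}\thugephage\tCRISPR_spacer\t{s + 1}\t"
                         f"{s + len(seq)}\t.\t.\t.\tID={aid}_sp{i + 1};"
                         f"Parent={aid}\n")


def arrays_to_table(arrays) -> pd.DataFrame:
    rows = []
    for a in arrays:
        for sid, (s, seq) in zip(a.spacer_ids(), a.spacers):
            rows.append({"contig_id": a.contig_id, "array_start": a.start,
                         "array_end": a.end, "n_repeats": a.n_repeats,
                         "consensus_repeat": a.consensus_repeat,
                         "spacer_id": sid, "spacer_start": s,
                         "spacer_seq": seq})
    return pd.DataFrame(rows, columns=["contig_id", "array_start", "array_end",
                                       "n_repeats", "consensus_repeat",
                                       "spacer_id", "spacer_start", "spacer_seq"])


def matches_to_table(matches) -> pd.DataFrame:
    rows = [{"spacer_id": m.spacer_id, "source_contig": m.source_contig,
             "target_contig": m.target_contig, "target_start": m.target_start,
             "strand": m.strand, "align_len": m.align_len,
             "mismatches": m.mismatches, "tier": m.tier} for m in matches]
    return pd.DataFrame(rows, columns=["spacer_id", "source_contig",
                                       "target_contig", "target_start", "strand",
                                       "align_len", "mismatches", "tier"])


def edges_to_table(edges) -> pd.DataFrame:
    rows = [{"source": e.source, "target": e.target, "n_strict": e.n_strict,
             "n_expanded": e.n_expanded, "style": e.style,
             "self_targeting": e.self_targeting} for e in edges]
    return pd.DataFrame(rows, columns=["source", "target", "n_strict",
                                       "n_expanded", "style", "self_targeting"])
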