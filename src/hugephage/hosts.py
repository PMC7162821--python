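"""Bacterial host prediction for phage genomes.

Two independent evidence lines are combined:

* taxonomy voting — phylum-level best-hit counts over the phage's genes;
  a phylum is assigned only when it has at least three times as many
  counts as the runner-up;
* CRISPR targeting — a bacterial contig whose array strictly targets the
  phage (alignment > 24 bp, <= 1 mismatch) implicates its phylum.

The two are reconciled: agreement fixes the host, a single evidence line
is reported as tentative, and conflicting lines leave the host unassigned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .crispr import SpacerMatch


@dataclass
class HostPrediction:
    phage_id: str
    vote_phylum: str | None
    vote_counts: dict
    crispr_phylum: str | None
    crispr_conflict: list = field(default_factory=list)
    final: str | None = None
    agreement: str = "none"  # agree | conflict | single_evidence | none


def vote_host(hits: pd.DataFrame, phage_id: str,
              ratio: float = 3.0) -> tuple[str | None, dict]:
    """Phylum vote over a phage's gene hits.

    Counts phylum-level matches (one vote per gene, best hit); the top
    phylum is assigned only if its count is at least ``ratio`` times the
    second-highest count (a single voted phylum always passes). Genes
    without a phylum call abstain.
    """
    sub = hits[(hits["contig_id"] == phage_id) & hits["phylum"].notna()]
    counts = sub["phylum"].value_counts().to_dict()
    if not counts:
        return None, {}
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    top_taxon, top = ranked[0]
    second = ranked[1][1] if len(ranked) > 1 else 0
    if top >= ratio * second:
        return top_taxon, counts
    return None, counts


def crispr_host(matches: list[SpacerMatch], bacterial_taxa: dict,
                phage_id: str) -> tuple[str | None, list]:
    """Host phylum implied by strict CRISPR targeting of the phage.

    ``bacterial_taxa`` maps bacterial contig ids to phyla; only strict-tier
    matches from arrays on those contigs count. Multiple implicated phyla
    are returned as a conflict list (and no single phylum is reported).
    """
    phyla = set()
    for m in matches:
        if m.tier != "strict" or m.target_contig != phage_id:
            continue
        phylum = bacterial_taxa.get(m.source_contig)
        if phylum is not None:
            phyla.add(phylum)
    if len(phyla) == 1:
        return next(iter(phyla)), []
    if len(phyla) > 1:
        return None, sorted(phyla)
    return None, []


def reconcile(phage_id: str, vote_phylum: str | None, vote_counts: dict,
              crispr_phylum: str | None,
              crispr_conflict: list | None = None) -> HostPrediction:
    """Combine vote- and CRISPR-based evidence into a final host call."""
    crispr_conflict = crispr_conflict or []
    if crispr_conflict:
        agreement, final = "conflict", None
    elif vote_phylum and crispr_phylum:
        if vote_phylum == crispr_phylum:
            agreement, final = "agree", vote_phylum
        else:
            agreement, final = "conflict", None
    elif vote_phylum or crispr_phylum:
        agreement, final = "single_evidence", vote_phylum or crispr_phylum
    else:
        agreement, final = "none", None
    return HostPrediction(phage_id=phage_id, vote_phylum=vote_phylum,
                          vote_counts=vote_counts, crispr_phylum=crispr_phylum,
                          crispr_conflict=list(crispr_conflict),
                          final=final, agreement=agreement)


def predict_hosts(hits: pd.DataFrame, matches: list[SpacerMatch],
                  phage_ids: list, bacterial_taxa: dict,
                  ratio: float = 3.0) -> list[HostPrediction]:
    """Run both evidence lines and reconcile, for every phage."""
    out = []
    for pid in phage_ids:
        vp, counts = vote_host(hits, pid, ratio=ratio)
        cp, conflict = crispr_host(matches, bacterial_taxa, pid)
        out.append(reconcile(pid, vp, counts, cp, conflict))
    return out
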