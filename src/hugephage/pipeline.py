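"""End-to-end orchestration and community-level summary statistics.

``run_pipeline`` wires the stages together — synthetic-community
generation (or loading user FASTA/TSV inputs), assembly QC, gene calling
with genetic-code inference, CRISPR array detection, element
classification, spacer matching and the interaction network, host
prediction, protein-family clustering and summary statistics — writing
each stage's artifacts under the output directory with stable file names
and a machine-readable JSON report. Runs are deterministic under a fixed
seed: the report embeds a hash of the configuration instead of
timestamps, so two identical runs produce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, classify, crispr, families, genes, hosts, io, qc
from .simulate import (CommunitySpec, generate_community,
                       simulate_protein_similarity)

log = logging.getLogger("hugephage")

STAGES = ("simulate", "qc", "genes", "crispr", "classify", "hosts",
          "families", "summary")


@dataclass
class RunConfig:
    output_dir: str = "hugephage_out"
    seed: int = 0
    community: CommunitySpec | None = None
    contigs_fasta: str | None = None
    annotations_tsv: str | None = None
    protein_edges_tsv: str | None = None
    profile_edges_tsv: str | None = None
    trna_table_tsv: str | None = None
    skip_stages: list = field(default_factory=list)
    qc_params: dict = field(default_factory=dict)
    genes_params: dict = field(default_factory=dict)
    classify_params: dict = field(default_factory=dict)
    crispr_params: dict = field(default_factory=dict)
    hosts_params: dict = field(default_factory=dict)
    families_params: dict = field(default_factory=dict)
    summary_params: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.community is None and self.contigs_fasta is None:
            raise ValueError("config needs either a community spec or contigs_fasta")
        for attr in ("contigs_fasta", "annotations_tsv", "protein_edges_tsv",
                     "profile_edges_tsv", "trna_table_tsv"):
            p = getattr(self, attr)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{attr}: {p} does not exist")
        unknown = set(self.skip_stages) - set(STAGES)
        if unknown:
            raise ValueError(f"skip_stages: unknown stages {sorted(unknown)}")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        comm = d.pop("community", None)
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        if comm is not None:
            cfg.community = CommunitySpec.from_dict(comm)
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def canonical(self) -> dict:
        # output_dir is excluded: provenance covers the scientific config only
        d = {k: getattr(self, k) for k in self.__dataclass_fields__
             if k != "output_dir"}
        if self.community is not None:
            from dataclasses import asdict

            d["community"] = asdict(self.community)
        return json.loads(json.dumps(d, sort_keys=True, default=str))


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.canonical(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: RunConfig) -> dict:
    """Run all (non-skipped) stages; returns the report dict.

    Stage artifacts are written under ``config.output_dir``; a failing
    stage aborts the run with :class:`StageError` but leaves earlier
    stages' outputs in place.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"version": __version__, "seed": config.seed,
                    "config_hash": _config_hash(config), "stages": {}}
    skip = set(config.skip_stages)
    state: dict = {}

    def run_stage(name, fn):
        if name in skip:
            report["stages"][name] = {"skipped": True}
            return
        log.info("stage %s", name)
        try:
            report["stages"][name] = fn(config, out, state)
        except Exception as exc:  # noqa: BLE001 - report which stage died
            _write_report(report, out)
            raise StageError(name, exc) from exc

    for name, fn in (("simulate", _stage_simulate), ("qc", _stage_qc),
                     ("genes", _stage_genes), ("crispr", _stage_crispr),
                     ("classify", _stage_classify), ("hosts", _stage_hosts),
                     ("families", _stage_families), ("summary", _stage_summary)):
        run_stage(name, fn)
    _write_report(report, out)
    return report


def _write_report(report: dict, out: Path) -> None:
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True, default=str)


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def _stage_simulate(config: RunConfig, out: Path, state: dict) -> dict:
    if config.community is not None:
        spec = config.community
        contigs, ann, truth = generate_community(spec)
        io.write_fasta(contigs, out / "contigs.fasta")
        io.write_table(ann, out / "annotations.tsv")
        truth.to_json(out / "truth.json")
        state["truth"] = truth
        summary = {"synthetic": True, "n_contigs": len(contigs)}
    else:
        contigs = io.read_fasta(config.contigs_fasta)
        ann = (io.read_annotations(config.annotations_tsv)
               if config.annotations_tsv else pd.DataFrame(
                   columns=["contig_id", "gene_id", "domain", "phylum", "class",
                            "order", "family", "genus", "keyword", "bitscore"]))
        summary = {"synthetic": False, "n_contigs": len(contigs)}
    state["contigs"] = contigs
    state["annotations"] = ann
    return summary


def _stage_qc(config: RunConfig, out: Path, state: dict) -> dict:
    p = dict(config.qc_params)
    min_repeat = p.pop("min_repeat", 5_000)
    window = p.pop("window", 1_000)
    step = p.pop("step", 500)
    short_repeats = p.pop("short_repeats", False)
    if p:
        raise ValueError(f"qc: unknown parameters {sorted(p)}")
    rows = []
    state["qc"] = {}
    for c in state["contigs"]:
        circ = qc.detect_circularity(c)
        hits = qc.detect_long_direct_repeats(c, min_len=min_repeat)
        concat = qc.flag_concatemer(c, hits)
        profile = qc.gc_skew(c, window=window, step=step)
        mode = qc.classify_replication_mode(profile)
        n_short = (len(qc.tabulate_short_repeats(c)) if short_repeats else None)
        state["qc"][c.id] = {"circularity": circ, "concatemer": concat,
                             "skew": profile, "long_repeats": hits}
        rows.append({
            "contig_id": c.id, "length": len(c.seq),
            "end_overlap": circ.overlap,
            "potentially_complete": circ.potentially_complete,
            "n_long_repeats": len(hits),
            "is_concatemer": concat.is_artifact,
            "corrected_length": concat.corrected_length,
            "skew_mode": mode,
            "skew_fit_quality": round(profile.fit_quality, 4),
            "skew_breakpoints": ";".join(map(str, profile.breakpoints)),
            "n_short_repeats": n_short,
        })
    df = pd.DataFrame(rows)
    io.write_table(df, out / "qc.tsv")
    return {"n_circular": int(df["potentially_complete"].sum()),
            "n_concatemer": int(df["is_concatemer"].sum()),
            "skew_modes": df["skew_mode"].value_counts().to_dict()}


def _stage_genes(config: RunConfig, out: Path, state: dict) -> dict:
    p = dict(config.genes_params)
    min_len = p.pop("min_len_codons", 60)
    flag_threshold = p.pop("flag_threshold", 0.78)
    margin = p.pop("margin", 0.10)
    if p:
        raise ValueError(f"genes: unknown parameters {sorted(p)}")
    all_genes = []
    state["genes"] = {}
    state["code"] = {}
    rows = []
    for c in state["contigs"]:
        res = genes.infer_genetic_code(c, flag_threshold=flag_threshold,
                                       margin=margin, min_len_codons=min_len)
        chosen = genes.call_orfs(c, genes.GENETIC_CODES[res.chosen_code],
                                 min_len_codons=min_len)
        state["genes"][c.id] = chosen
        state["code"][c.id] = res
        all_genes.extend(chosen)
        row = {"contig_id": c.id, "chosen_code": res.chosen_code,
               "flagged_low_density": res.flagged,
               "n_genes": len(chosen),
               "ruled_out": ";".join(f"{c0}:{r}" for c0, r in res.ruled_out)}
        for code_id, d in sorted(res.density_by_code.items()):
            row[f"density_{code_id}"] = round(d, 4)
        rows.append(row)
    io.genes_to_gff3(all_genes, out / "genes.gff3")
    io.proteins_to_fasta(all_genes, out / "proteins.faa")
    io.write_table(pd.DataFrame(rows), out / "coding_density.tsv")
    return {"n_genes": len(all_genes),
            "codes": {r["contig_id"]: r["chosen_code"] for r in rows}}


def _stage_crispr(config: RunConfig, out: Path, state: dict) -> dict:
    p = dict(config.crispr_params)
    min_repeats = p.pop("min_repeats", 3)
    if p:
        raise ValueError(f"crispr: unknown parameters {sorted(p)}")
    arrays = []
    for c in state["contigs"]:
        arrays.extend(crispr.detect_arrays(c, min_repeats=min_repeats))
    state["arrays"] = arrays
    io.arrays_to_gff3(arrays, out / "crispr_arrays.gff3")
    io.write_table(io.arrays_to_table(arrays), out / "crispr_spacers.tsv")
    matches = (crispr.match_spacers(arrays, state["contigs"]) if arrays else [])
    state["matches"] = matches
    io.write_table(io.matches_to_table(matches), out / "spacer_matches.tsv")
    return {"n_arrays": len(arrays), "n_matches": len(matches),
            "n_strict": sum(m.tier == "strict" for m in matches)}


def _stage_classify(config: RunConfig, out: Path, state: dict) -> dict:
    p = dict(config.classify_params)
    window = p.pop("prophage_window", 20_000)
    high_hypo = p.pop("high_hypo_threshold", 0.6)
    if p:
        raise ValueError(f"classify: unknown parameters {sorted(p)}")
    ann = state["annotations"]
    arrays_by_contig: dict = {}
    for a in state.get("arrays", []):
        arrays_by_contig.setdefault(a.contig_id, []).append(a)
    results = {}
    votes_all = {}
    rows = []
    for c in state["contigs"]:
        votes = classify.vote_taxonomy(ann, c.id)
        votes_all[c.id] = votes
        markers = classify.find_phage_markers(ann, c.id)
        plasmid = classify.find_plasmid_genes(ann, c.id)
        n_genes = len(state.get("genes", {}).get(c.id, [])) or \
            int((ann["contig_id"] == c.id).sum())
        hypo = (classify.hypothetical_fraction(ann, n_genes, c.id)
                if n_genes else 1.0)
        bounds = classify.detect_prophage_transition(c, ann, window=window)
        res = classify.classify_element(
            c, votes, markers, hypo, plasmid,
            crispr_present=bool(arrays_by_contig.get(c.id)),
            prophage_bounds=bounds, high_hypo_threshold=high_hypo)
        results[c.id] = res
        rows.append({
            "contig_id": c.id, "element_type": res.element_type,
            "rejected": res.rejected, "length_exception": res.length_exception,
            "hypothetical_fraction": round(hypo, 4),
            "markers": ";".join(sorted(markers)),
            "plasmid_genes": ";".join(sorted(plasmid)),
            "domain_winner": votes["domain"].winner,
            "phylum_winner": votes["phylum"].winner,
            "prophage_bounds": ";".join(map(str, bounds)),
            "rule_trace": " | ".join(res.rule_trace)})
    state["classification"] = results
    state["votes"] = votes_all
    io.write_table(pd.DataFrame(rows), out / "classification.tsv")
    counts = pd.Series([r.element_type for r in results.values()]).value_counts()
    return {"element_types": counts.to_dict()}


def _stage_hosts(config: RunConfig, out: Path, state: dict) -> dict:
    p = dict(config.hosts_params)
    ratio = p.pop("ratio", 3.0)
    if p:
        raise ValueError(f"hosts: unknown parameters {sorted(p)}")
    ann = state["annotations"]
    results = state.get("classification", {})
    votes = state.get("votes", {})
    phage_ids = sorted(cid for cid, r in results.items()
                       if r.element_type in ("phage", "prophage_containing"))
    bacterial_taxa = {}
    for cid, v in votes.items():
        if cid in phage_ids:
            continue
        if v["domain"].winner == "Bacteria" and v["phylum"].winner:
            bacterial_taxa[cid] = v["phylum"].winner
    preds = hosts.predict_hosts(ann, state.get("matches", []), phage_ids,
                                bacterial_taxa, ratio=ratio)
    # node types for the interaction network
    node_types = {cid: "phage" for cid in phage_ids}
    node_types.update({cid: "bacteria" for cid in bacterial_taxa})
    edges = crispr.build_network(state.get("matches", []), node_types)
    io.write_table(io.edges_to_table(edges), out / "interaction_network.tsv")
    crispr.network_to_graphml(edges, node_types, out / "interaction_network.graphml")
    rows = [{"phage_id": h.phage_id, "vote_phylum": h.vote_phylum,
             "crispr_phylum": h.crispr_phylum, "final": h.final,
             "agreement": h.agreement,
             "vote_counts": ";".join(f"{k}:{v}" for k, v in
                                     sorted(h.vote_counts.items()))}
            for h in preds]
    io.write_table(pd.DataFrame(rows), out / "host_predictions.tsv")
    state["host_predictions"] = preds
    state["network"] = edges
    return {"n_predicted": sum(h.final is not None for h in preds),
            "n_edges": len(edges)}


def _stage_families(config: RunConfig, out: Path, state: dict) -> dict:
    p = dict(config.families_params)
    inflation = p.pop("inflation", 2.0)
    if p:
        raise ValueError(f"families: unknown parameters {sorted(p)}")
    if config.protein_edges_tsv:
        prot_df = pd.read_csv(config.protein_edges_tsv, sep="\t")
        prof_df = (pd.read_csv(config.profile_edges_tsv, sep="\t")
                   if config.profile_edges_tsv else prot_df.iloc[0:0])
        proteins = sorted(set(prot_df["query"]) | set(prot_df["target"]))
    elif config.community is not None:
        proteins, prot_df, prof_df, truth = simulate_protein_similarity(
            seed=config.seed)
        state["family_truth"] = truth
        io.write_table(prot_df, out / "protein_edges.tsv")
        io.write_table(prof_df, out / "profile_edges.tsv")
    else:
        return {"skipped": "no similarity tables provided"}
    fams, sub, res = families.cluster_proteins(
        proteins, families.edges_from_table(prot_df),
        families.edges_from_table(prof_df), inflation=inflation)
    rows = [{"protein_id": prot, "subfamily": sub[prot], "family": f.family_id}
            for f in fams for prot in f.members]
    rows.sort(key=lambda r: r["protein_id"])
    io.write_table(pd.DataFrame(rows), out / "protein_families.tsv")
    state["families"] = fams
    return {"n_proteins": len(proteins), "n_subfamilies": len(set(sub.values())),
            "n_families": len(fams), "mcl_converged": res.converged}


def _stage_summary(config: RunConfig, out: Path, state: dict) -> dict:
    p = dict(config.summary_params)
    n_perm = p.pop("n_permutations", 10_000)
    if p:
        raise ValueError(f"summary: unknown parameters {sorted(p)}")
    if config.trna_table_tsv:
        table = pd.read_csv(config.trna_table_tsv, sep="\t")
    elif "truth" in state:
        truth = state["truth"]
        table = pd.DataFrame(
            [{"genome_id": cid, "length": t.length, "trna_count": t.trna_count}
             for cid, t in sorted(truth.contigs.items())])
    else:
        table = pd.DataFrame({"genome_id": [c.id for c in state["contigs"]],
                              "length": [len(c.seq) for c in state["contigs"]],
                              "trna_count": np.nan})
    stats = summary_stats(table, n_permutations=n_perm, seed=config.seed)
    with open(out / "summary_stats.json", "w") as fh:
        json.dump(stats, fh, indent=1, sort_keys=True)
    return stats


# ---------------------------------------------------------------------------
# Summary statistics
# ---------------------------------------------------------------------------

def summary_stats(table: pd.DataFrame, n_permutations: int = 10_000,
                  seed: int = 0) -> dict:
    """Genome-size summary and the tRNA-count vs size correlation.

    Reports histogram bins (100 kb), the median genome size, and the
    Spearman rank correlation between tRNA count and genome length with a
    seeded permutation p-value (two-sided), mirroring the
    genome-size/tRNA relationship reported for huge phages.
    """
    from scipy.stats import rankdata, spearmanr

    lengths = table["length"].to_numpy(dtype=float)
    out: dict = {"n_genomes": int(len(table)),
                 "median_size_bp": float(np.median(lengths)) if len(table) else None}
    edges = np.arange(0, lengths.max() + 100_000, 100_000) if len(table) else []
    if len(table):
        hist, _ = np.histogram(lengths, bins=edges)
        out["size_histogram_100kb"] = hist.tolist()
    counts = table.get("trna_count")
    if counts is None or counts.isna().all() or len(table) < 3:
        out["spearman_rho"] = None
        out["p_value"] = None
        out["note"] = "tRNA correlation needs >= 3 genomes with counts"
        return out
    counts = counts.to_numpy(dtype=float)
    if np.all(lengths == lengths[0]) or np.all(counts == counts[0]):
        out["spearman_rho"] = None
        out["p_value"] = None
        out["note"] = "correlation undefined for constant input"
        return out
    rho = float(spearmanr(lengths, counts).statistic)
    rng = np.random.default_rng(seed)
    r1 = rankdata(lengths)
    r2 = rankdata(counts)
    r1 = (r1 - r1.mean()) / r1.std()
    r2 = (r2 - r2.mean()) / r2.std()
    n = len(r1)
    perms = np.array([rng.permutation(r2) for _ in range(n_permutations)])
    rho_perm = perms @ r1 / n
    p = (np.sum(np.abs(rho_perm) >= abs(rho)) + 1) / (n_permutations + 1)
    out["spearman_rho"] = round(rho, 6)
    out["p_value"] = float(p)
    out["n_permutations"] = n_permutations
    return out
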