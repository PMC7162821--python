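"""Synthetic metagenomic communities with a machine-readable truth ledger.

Every downstream stage of the toolkit (QC, gene calling, classification,
CRISPR analysis, host prediction, summary statistics) is exercised against
communities built here: a set of huge-phage genomes (>=200 kb), bacterial
host contigs and optional plasmid-like elements in which every analytic
signal is planted with known coordinates:

* circular genomes represented linearly with terminal direct repeats;
* tandem-concatemer assembly artifacts (k identical copies of a unit);
* GC skew in bidirectional, unidirectional or absent replication modes;
* genomes translated with the standard bacterial code or with the amber
  stop codon (TAG) reassigned to glutamine;
* CRISPR arrays whose spacers match protospacers in other genomes with a
  controlled number of mismatches;
* per-gene annotation tables with controlled taxonomy-vote fractions,
  phage marker genes, plasmid genes and hypothetical-protein fractions.

Genomes are concatenations of synthetic genes — random-codon ORFs with
log-normal lengths (median ~300 codons) separated by 20–150 bp intergenic
gaps — so coding density is high and tunable. The ledger
(:class:`PlantedTruth`) records every planted feature so recovery can be
scored exactly.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import _seq
from .genes import GENETIC_CODES
from .records import ContigRecord

PHYLA = ("Firmicutes", "Bacteroidetes", "Proteobacteria", "Actinobacteria",
         "Cyanobacteria")

FUNCTIONAL_KEYWORDS = (
    "DNA polymerase", "helicase", "ribonucleotide reductase",
    "thymidylate synthase", "DNA ligase", "RNA polymerase subunit",
    "nuclease", "methyltransferase", "glycosyltransferase",
)

PHAGE_MARKER_KEYWORDS = (
    "large terminase subunit", "major capsid protein", "portal protein",
    "tail fiber protein", "baseplate wedge protein",
)

PLASMID_KEYWORDS = (
    "ParA partition protein", "ParB partition protein",
    "conjugative transfer protein TraG",
)

HYPOTHETICAL = "hypothetical protein"

#: base order matching :mod:`hugephage._seq` encoding
_BASE_ORDER = "ACGT"
_CODONS = [a + b + c for a in _BASE_ORDER for b in _BASE_ORDER for c in _BASE_ORDER]
_CODON_ARR = np.array(_CODONS)


class SpecValidationError(ValueError):
    """A community spec contradicts itself; the message names the field."""


class FeatureCollisionError(RuntimeError):
    """A requested planted feature would overwrite another planted feature."""


# ---------------------------------------------------------------------------
# Spec types
# ---------------------------------------------------------------------------

@dataclass
class ArraySpec:
    """A CRISPR array to plant.

    ``spacer_sources`` has one entry per spacer (``n_repeats - 1``): either
    the string ``"random"`` or a ``(target_contig_name, mismatches)`` pair,
    meaning the spacer is a copy of a protospacer in that contig carrying
    exactly that many mismatches. Shorter lists are padded with "random".
    """

    repeat_seq: str | None = None
    repeat_len: int = 32
    n_repeats: int = 6
    spacer_len: int = 34
    spacer_sources: list = field(default_factory=list)


@dataclass
class AnnotationProfile:
    """Controls the per-gene annotation table of one genome."""

    hit_fraction: float = 0.45
    hypothetical_fraction: float = 0.70  # over ALL genes, hit or not
    domain_fractions: dict = field(default_factory=lambda: {"Bacteria": 0.5, "Viruses": 0.5})
    phylum_fractions: dict = field(default_factory=dict)  # within Bacteria-domain hits
    markers: tuple = ()
    plasmid_genes: tuple = ()


@dataclass
class GenomeSpec:
    name: str
    kind: str = "phage"  # phage | host | plasmid
    length: int = 250_000
    gc_content: float = 0.5
    skew_mode: str = "none"  # bidirectional | unidirectional | none
    skew_amplitude: float = 0.05
    skew_breakpoints: tuple = (0.25, 0.75)  # fractions of unit length
    genetic_code: str = "code11"
    terminal_overlap_bp: int = 0
    concatemer_units: int = 1
    arrays: list = field(default_factory=list)
    annotation: AnnotationProfile | None = None
    host_phylum: str | None = None  # true host (phage) or own phylum (host)
    prophage_flank_bp: int = 0  # >0: embed genome between bacterial flanks
    minus_strand_fraction: float = 0.2


@dataclass
class CommunitySpec:
    """Top-level description of a synthetic community.

    If ``genomes`` is empty, a default community is materialized: phage
    lengths evenly spaced over ``phage_length_range``, replication modes
    cycling bidirectional/unidirectional/none, one TAG-recoded phage, one
    tandem-dimer artifact, one prophage-containing contig, circularized
    phages with 120 bp terminal repeats, host contigs whose CRISPR arrays
    target the phages (with 0–3 mismatch spacers), and one phage-encoded
    array targeting a rival phage.
    """

    seed: int = 0
    n_phage: int = 10
    n_host: int = 5
    n_plasmid: int = 0
    phage_length_range: tuple = (200_000, 700_000)
    host_length_range: tuple = (250_000, 350_000)
    gc_content: float = 0.5
    terminal_overlap_bp: int = 120
    concatemer_units: int = 2
    genomes: list = field(default_factory=list)

    def materialize(self) -> list[GenomeSpec]:
        if self.genomes:
            return list(self.genomes)
        specs: list[GenomeSpec] = []
        n = self.n_phage
        lengths = np.linspace(*self.phage_length_range, max(n, 2)).astype(int)
        skew_cycle = ("bidirectional", "unidirectional", "none")
        concat_idx = n - 1 if n >= 6 else None
        prophage_idx = 4 if n >= 5 else None
        for i in range(n):
            name = f"phage_{i + 1:02d}"
            s = GenomeSpec(
                name=name, kind="phage", length=int(lengths[i]),
                gc_content=self.gc_content,
                skew_mode=skew_cycle[i % 3],
                genetic_code="TAG_recoded" if i == 1 else "code11",
                terminal_overlap_bp=self.terminal_overlap_bp if i % 2 == 0 else 0,
                host_phylum=PHYLA[i % min(max(self.n_host, 1), len(PHYLA))],
            )
            if i == concat_idx:
                s.skew_mode = "none"
                s.terminal_overlap_bp = 0
                s.concatemer_units = self.concatemer_units
                s.length = 250_000
            if i == prophage_idx:
                s.skew_mode = "none"
                s.terminal_overlap_bp = 0
                s.prophage_flank_bp = 40_000
                s.length = 250_000
            specs.append(s)
        if n >= 2:
            # phage-encoded CRISPR array targeting a rival phage
            specs[0].arrays.append(ArraySpec(
                n_repeats=7,
                spacer_sources=[("phage_02", 0), ("phage_02", 1), ("phage_02", 3)],
            ))
        for j in range(self.n_plasmid):
            specs.append(GenomeSpec(
                name=f"plasmid_{j + 1:02d}", kind="plasmid",
                length=220_000 + 10_000 * j, gc_content=self.gc_content,
                host_phylum=PHYLA[j % len(PHYLA)],
            ))
        h_lengths = np.linspace(*self.host_length_range, max(self.n_host, 2)).astype(int)
        for j in range(self.n_host):
            name = f"host_{j + 1:02d}"
            s = GenomeSpec(
                name=name, kind="host", length=int(h_lengths[j]),
                gc_content=self.gc_content,
                host_phylum=PHYLA[j % len(PHYLA)],
            )
            if j < n:
                target = f"phage_{j + 1:02d}"
                s.arrays.append(ArraySpec(
                    n_repeats=6,
                    spacer_sources=[(target, 0), (target, 0), (target, 2)],
                ))
            specs.append(s)
        return specs

    @classmethod
    def from_dict(cls, d: dict) -> "CommunitySpec":
        d = dict(d)
        genomes = []
        for g in d.pop("genomes", []):
            g = dict(g)
            arrays = [ArraySpec(**a) for a in g.pop("arrays", [])]
            ann = g.pop("annotation", None)
            genomes.append(GenomeSpec(
                arrays=arrays,
                annotation=AnnotationProfile(**ann) if ann else None, **g))
        known = cls.__dataclass_fields__
        unknown = set(d) - set(known)
        if unknown:
            raise SpecValidationError(f"unknown spec fields: {sorted(unknown)}")
        for key in ("phage_length_range", "host_length_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(genomes=genomes, **d)


# ---------------------------------------------------------------------------
# Truth ledger
# ---------------------------------------------------------------------------

@dataclass
class SpacerTruth:
    spacer_id: str
    start: int
    end: int
    seq: str
    source_contig: str | None = None
    proto_start: int | None = None
    proto_end: int | None = None
    mismatches: int | None = None


@dataclass
class ArrayTruth:
    array_id: str
    contig_id: str
    start: int
    end: int
    repeat: str
    n_repeats: int
    spacers: list = field(default_factory=list)


@dataclass
class ProtospacerTruth:
    spacer_id: str
    start: int
    end: int
    mismatches: int


@dataclass
class GeneTruth:
    start: int
    end: int
    strand: str
    region: str = "core"  # core | flank


@dataclass
class ContigTruth:
    contig_id: str
    kind: str
    element_type: str | None
    length: int
    unit_length: int
    concatemer_units: int
    terminal_overlap: int
    skew_mode: str
    skew_amplitude: float
    skew_breakpoints: list
    genetic_code: str
    gc_content: float
    host_phylum: str | None
    trna_count: int
    prophage_bounds: list | None = None
    genes: list = field(default_factory=list)
    arrays: list = field(default_factory=list)
    protospacers: list = field(default_factory=list)


@dataclass
class PlantedTruth:
    seed: int
    contigs: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "PlantedTruth":
        contigs = {}
        for cid, c in d["contigs"].items():
            c = dict(c)
            c["genes"] = [GeneTruth(**g) for g in c["genes"]]
            c["protospacers"] = [ProtospacerTruth(**p) for p in c["protospacers"]]
            arrays = []
            for a in c["arrays"]:
                a = dict(a)
                a["spacers"] = [SpacerTruth(**s) for s in a["spacers"]]
                arrays.append(ArrayTruth(**a))
            c["arrays"] = arrays
            contigs[cid] = ContigTruth(**c)
        return cls(seed=d["seed"], contigs=contigs)

    @classmethod
    def from_json(cls, path) -> "PlantedTruth":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# Sequence synthesis
# ---------------------------------------------------------------------------

def _letter_probs(gc: float, a: float) -> np.ndarray:
    """Per-base probabilities (A, C, G, T) for GC fraction ``gc`` and
    G-vs-C skew amplitude ``a`` (skew = (G-C)/(G+C) = a)."""
    at = (1.0 - gc) / 2.0
    return np.array([at, gc / 2.0 * (1.0 - a), gc / 2.0 * (1.0 + a), at])


def _codon_dist(gc: float, a: float, stops: frozenset) -> np.ndarray:
    """Codon sampling distribution excluding stop codons.

    Excluding the AT-rich stop codons shifts composition slightly, so the
    underlying letter GC is adjusted by fixed-point iteration until the
    expected GC of the emitted codons matches the target.
    """
    stop_idx = [_CODONS.index(s) for s in stops]
    gc_per_codon = np.array([sum(ch in "GC" for ch in c) / 3.0 for c in _CODONS])
    g = gc
    probs = None
    for _ in range(6):
        lp = _letter_probs(g, a)
        probs = np.ones(64)
        for j, c in enumerate(_CODONS):
            probs[j] = lp[_BASE_ORDER.index(c[0])] * lp[_BASE_ORDER.index(c[1])] \
                * lp[_BASE_ORDER.index(c[2])]
        probs[stop_idx] = 0.0
        probs /= probs.sum()
        egc = float(probs @ gc_per_codon)
        g = min(max(g + (gc - egc), 0.02), 0.98)
    return probs


class _SeqFactory:
    """Caches codon/letter distributions for one generation run."""

    def __init__(self, rng: np.random.Generator):
        self.rng = rng
        self._codon_cache: dict = {}

    def letters(self, n: int, gc: float, a: float) -> str:
        idx = self.rng.choice(4, size=n, p=_letter_probs(gc, a)).astype(np.uint8)
        return _seq.decode(idx)

    def gene(self, n_body_codons: int, gc: float, a: float, stops: frozenset) -> str:
        key = (round(gc, 6), round(a, 6), stops)
        if key not in self._codon_cache:
            self._codon_cache[key] = _codon_dist(gc, a, stops)
        probs = self._codon_cache[key]
        idx = self.rng.choice(64, size=n_body_codons, p=probs)
        body = "".join(_CODON_ARR[idx].tolist())
        stop = sorted(stops)[int(self.rng.integers(len(stops)))]
        return "ATG" + body + stop


def _skew_sign(pos: float, length: int, mode: str, breakpoints: tuple) -> float:
    if mode == "none":
        return 0.0
    if mode == "unidirectional":
        return 1.0
    b1, b2 = (breakpoints[0] * length, breakpoints[1] * length)
    return 1.0 if b1 <= pos < b2 else -1.0


def _build_unit(factory: _SeqFactory, spec: GenomeSpec, length: int,
                region: str = "core") -> tuple[str, list]:
    """Generate one genome unit: genes separated by intergenic gaps.

    Returns the sequence (exactly ``length`` bp) and the gene truth list.
    """
    rng = factory.rng
    code = GENETIC_CODES[spec.genetic_code]
    stops = code.stop_codons
    parts: list[str] = []
    genes: list[GeneTruth] = []
    pos = 0
    while True:
        gap = int(rng.integers(20, 151))
        n_body = int(np.clip(np.exp(rng.normal(np.log(300), 0.45)), 60, 2500))
        glen = 3 * (n_body + 2)
        if pos + gap + glen > length:
            a = spec.skew_amplitude * _skew_sign(pos, length, spec.skew_mode,
                                                spec.skew_breakpoints)
            parts.append(factory.letters(length - pos, spec.gc_content, a))
            break
        mid = pos + gap + glen / 2
        a = spec.skew_amplitude * _skew_sign(mid, length, spec.skew_mode,
                                             spec.skew_breakpoints)
        parts.append(factory.letters(gap, spec.gc_content, a))
        pos += gap
        strand = "+" if rng.random() >= spec.minus_strand_fraction else "-"
        g = factory.gene(n_body, spec.gc_content, a if strand == "+" else -a, stops)
        if strand == "-":
            g = _seq.revcomp(g)
        parts.append(g)
        genes.append(GeneTruth(pos, pos + glen, strand, region))
        pos += glen
    seq = "".join(parts)
    assert len(seq) == length
    return seq, genes


# ---------------------------------------------------------------------------
# Feature planting
# ---------------------------------------------------------------------------

def _overlaps(lo: int, hi: int, occupied: list) -> bool:
    return any(lo < e and s < hi for s, e in occupied)


def _alloc(rng: np.random.Generator, length: int, size: int, occupied: list,
           margin: int, what: str) -> int:
    lo, hi = margin, length - margin - size
    if hi <= lo:
        raise SpecValidationError(
            f"{what}: feature of {size} bp does not fit in genome of {length} bp")
    for _ in range(200):
        s = int(rng.integers(lo, hi))
        if not _overlaps(s, s + size, occupied):
            occupied.append((s, s + size))
            return s
    raise FeatureCollisionError(f"{what}: no free location after 200 tries")


def _mutate(rng: np.random.Generator, seq: str, m: int) -> str:
    if m == 0:
        return seq
    pos = rng.choice(len(seq), size=m, replace=False)
    out = list(seq)
    for p in pos:
        choices = [b for b in _BASE_ORDER if b != out[p]]
        out[p] = choices[int(rng.integers(3))]
    return "".join(out)


def _array_sequence(repeat: str, spacers: list) -> str:
    return repeat + "".join(sp + repeat for sp in spacers)


# ---------------------------------------------------------------------------
# Annotation tables
# ---------------------------------------------------------------------------

ANNOTATION_COLUMNS = ["contig_id", "gene_id", "domain", "phylum", "class",
                      "order", "family", "genus", "keyword", "bitscore",
                      "start", "end", "strand"]


def _default_profile(spec: GenomeSpec) -> AnnotationProfile:
    if spec.kind == "host":
        own = spec.host_phylum or PHYLA[0]
        rival = PHYLA[(PHYLA.index(own) + 1) % len(PHYLA)]
        return AnnotationProfile(
            hit_fraction=0.9, hypothetical_fraction=0.15,
            domain_fractions={"Bacteria": 1.0},
            phylum_fractions={own: 0.9, rival: 0.1})
    host = spec.host_phylum or PHYLA[0]
    rival = PHYLA[(PHYLA.index(host) + 1) % len(PHYLA)]
    if spec.kind == "plasmid":
        return AnnotationProfile(
            hit_fraction=0.6, hypothetical_fraction=0.5,
            domain_fractions={"Bacteria": 1.0},
            phylum_fractions={host: 0.8, rival: 0.2},
            plasmid_genes=PLASMID_KEYWORDS)
    return AnnotationProfile(
        hit_fraction=0.45, hypothetical_fraction=0.70,
        domain_fractions={"Bacteria": 0.5, "Viruses": 0.5},
        phylum_fractions={host: 0.8, rival: 0.2},
        markers=PHAGE_MARKER_KEYWORDS[:3])


_FLANK_PROFILE = AnnotationProfile(
    hit_fraction=0.95, hypothetical_fraction=0.10,
    domain_fractions={"Bacteria": 1.0})


def _sample_from_fractions(rng: np.random.Generator, fractions: dict) -> str | None:
    if not fractions:
        return None
    keys = sorted(fractions)
    probs = np.array([fractions[k] for k in keys], dtype=float)
    total = probs.sum()
    if total > 1.0 + 1e-9:
        raise SpecValidationError("annotation_profile: fractions sum to > 1")
    if rng.random() >= total:
        return None
    probs /= total
    return keys[int(rng.choice(len(keys), p=probs))]


def _annotate_genome(rng: np.random.Generator, spec: GenomeSpec,
                     truth: ContigTruth) -> list[dict]:
    profile = spec.annotation or _default_profile(spec)
    flank_profile = _FLANK_PROFILE
    if spec.kind == "host" and spec.host_phylum:
        flank_profile = AnnotationProfile(
            hit_fraction=0.95, hypothetical_fraction=0.10,
            domain_fractions={"Bacteria": 1.0},
            phylum_fractions={spec.host_phylum: 0.9})
    rows: list[dict] = []
    core_idx = [i for i, g in enumerate(truth.genes) if g.region == "core"]
    special: dict[int, str] = {}
    keywords = list(profile.markers) + list(profile.plasmid_genes)
    if keywords:
        if len(core_idx) < len(keywords):
            raise SpecValidationError("annotation_profile: more markers than genes")
        chosen = rng.choice(len(core_idx), size=len(keywords), replace=False)
        for k, ci in zip(keywords, chosen):
            special[core_idx[int(ci)]] = k
    for i, gene in enumerate(truth.genes):
        prof = profile if gene.region == "core" else flank_profile
        gid = f"{truth.contig_id}_t{i + 1:05d}"
        base = {"contig_id": truth.contig_id, "gene_id": gid,
                "start": gene.start, "end": gene.end, "strand": gene.strand}
        if i in special:
            domain = "Bacteria" if special[i] in PLASMID_KEYWORDS else "Viruses"
            rows.append({**base, "domain": domain, "phylum": None, "class": None,
                         "order": None, "family": None, "genus": None,
                         "keyword": special[i],
                         "bitscore": float(np.round(rng.uniform(100, 300), 1))})
            continue
        if rng.random() >= prof.hit_fraction:
            continue  # gene has no database hit and abstains from voting
        p_hit = prof.hit_fraction
        h = (prof.hypothetical_fraction - (1.0 - p_hit)) / p_hit
        h = min(max(h, 0.0), 1.0)
        hypothetical = rng.random() < h
        domain = _sample_from_fractions(rng, prof.domain_fractions)
        phylum = None
        if domain == "Bacteria":
            phylum = _sample_from_fractions(rng, prof.phylum_fractions)
        lineage = {r: None for r in ("class", "order", "family", "genus")}
        if phylum is not None:
            for r in lineage:
                lineage[r] = f"{phylum}_{r}"
        keyword = HYPOTHETICAL if hypothetical else \
            FUNCTIONAL_KEYWORDS[int(rng.integers(len(FUNCTIONAL_KEYWORDS)))]
        bitscore = rng.uniform(40, 90) if hypothetical else rng.uniform(80, 250)
        rows.append({**base, "domain": domain, "phylum": phylum, **lineage,
                     "keyword": keyword, "bitscore": float(np.round(bitscore, 1))})
    return rows


# ---------------------------------------------------------------------------
# Community generation
# ---------------------------------------------------------------------------

def _validate(spec: GenomeSpec) -> None:
    if spec.length <= 0:
        raise SpecValidationError(f"{spec.name}: length must be positive")
    if not 0.0 < spec.gc_content < 1.0:
        raise SpecValidationError(f"{spec.name}: gc_content out of (0,1)")
    if spec.skew_mode not in ("bidirectional", "unidirectional", "none"):
        raise SpecValidationError(f"{spec.name}: unknown skew_mode {spec.skew_mode!r}")
    if spec.genetic_code not in GENETIC_CODES:
        raise SpecValidationError(f"{spec.name}: unknown genetic_code {spec.genetic_code!r}")
    if spec.concatemer_units < 1:
        raise SpecValidationError(f"{spec.name}: concatemer_units must be >= 1")
    if spec.terminal_overlap_bp < 0 or spec.terminal_overlap_bp > spec.length // 2:
        raise SpecValidationError(f"{spec.name}: terminal_overlap_bp out of range")
    for a in spec.arrays:
        alen = a.n_repeats * (a.repeat_seq and len(a.repeat_seq) or a.repeat_len) \
            + (a.n_repeats - 1) * a.spacer_len
        if alen + 2 * _MARGIN >= spec.length:
            raise SpecValidationError(
                f"{spec.name}: planted_arrays entry of {alen} bp does not fit "
                f"in genome of {spec.length} bp")


_MARGIN = 2_000  # keep planted features away from unit ends / terminal repeats


def generate_community(spec: CommunitySpec):
    """Generate a synthetic community.

    Returns ``(contigs, annotations, truth)``: a list of
    :class:`~hugephage.records.ContigRecord`, a pandas annotation table
    (one row per gene with a database hit) and the
    :class:`PlantedTruth` ledger. Identical specs (same seed) yield
    byte-identical outputs.
    """
    rng = np.random.default_rng(spec.seed)
    factory = _SeqFactory(rng)
    gspecs = spec.materialize()
    names = [g.name for g in gspecs]
    if len(set(names)) != len(names):
        raise SpecValidationError("genomes: duplicate genome names")
    for g in gspecs:
        _validate(g)

    seqs: dict[str, str] = {}
    truths: dict[str, ContigTruth] = {}
    occupied: dict[str, list] = {}

    # Pass 1: raw units (genes + gaps), prophage flanks included.
    for g in gspecs:
        if g.prophage_flank_bp > 0:
            fl = g.prophage_flank_bp
            flank_spec = GenomeSpec(name=g.name, kind="host",
                                    gc_content=g.gc_content, length=fl,
                                    host_phylum=g.host_phylum)
            left, lgenes = _build_unit(factory, flank_spec, fl, region="flank")
            core, cgenes = _build_unit(factory, g, g.length)
            right, rgenes = _build_unit(factory, flank_spec, fl, region="flank")
            seq = left + core + right
            genes = list(lgenes)
            for gg in cgenes:
                genes.append(GeneTruth(gg.start + fl, gg.end + fl, gg.strand, "core"))
            for gg in rgenes:
                genes.append(GeneTruth(gg.start + fl + g.length,
                                       gg.end + fl + g.length, gg.strand, "flank"))
            bounds = [fl, fl + g.length]
            etype = "prophage_containing"
        else:
            seq, genes = _build_unit(factory, g, g.length)
            bounds = None
            etype = {"phage": "phage", "plasmid": "plasmid_like",
                     "host": None}[g.kind]
        unit_len = len(seq)
        bps = []
        if g.skew_mode == "bidirectional":
            bps = [int(g.skew_breakpoints[0] * g.length),
                   int(g.skew_breakpoints[1] * g.length)]
            if g.prophage_flank_bp:
                bps = [b + g.prophage_flank_bp for b in bps]
        seqs[g.name] = seq
        gc = g.gc_content
        truths[g.name] = ContigTruth(
            contig_id=g.name, kind=g.kind, element_type=etype,
            length=unit_len, unit_length=unit_len,
            concatemer_units=g.concatemer_units,
            terminal_overlap=g.terminal_overlap_bp,
            skew_mode=g.skew_mode, skew_amplitude=g.skew_amplitude,
            skew_breakpoints=bps, genetic_code=g.genetic_code,
            gc_content=gc, host_phylum=g.host_phylum,
            trna_count=max(0, int(round(unit_len / 15_000 + rng.normal(0, 5)))),
            prophage_bounds=bounds, genes=genes)
        margin = max(_MARGIN, g.terminal_overlap_bp + 100)
        occupied[g.name] = [(0, margin), (unit_len - margin, unit_len)]

    # Pass 2: CRISPR arrays and cross-genome spacer links.
    for g in gspecs:
        for ai, aspec in enumerate(g.arrays):
            _plant_array(factory, g.name, ai, aspec, seqs, truths, occupied)

    # Pass 3: concatemer and terminal-overlap transformations.
    contigs = []
    for g in gspecs:
        seq = seqs[g.name]
        t = truths[g.name]
        if g.concatemer_units > 1:
            unit = seq
            k = g.concatemer_units
            seq = unit * k
            shift_items(t, len(unit), k)
        if g.terminal_overlap_bp > 0:
            seq = seq + seq[: g.terminal_overlap_bp]
        t.length = len(seq)
        contigs.append(ContigRecord(g.name, seq, source="synthetic"))

    # Pass 4: annotation tables (from planted gene truth).
    rows: list[dict] = []
    for g in gspecs:
        rows.extend(_annotate_genome(rng, g, truths[g.name]))
    annotations = pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)

    return contigs, annotations, PlantedTruth(seed=spec.seed, contigs=truths)


def shift_items(t: ContigTruth, unit_len: int, k: int) -> None:
    """Duplicate truth features into the extra copies of a concatemer."""
    genes, arrays, protos = list(t.genes), list(t.arrays), list(t.protospacers)
    for j in range(1, k):
        off = j * unit_len
        for g in genes:
            t.genes.append(GeneTruth(g.start + off, g.end + off, g.strand, g.region))
        for a in arrays:
            sp = [SpacerTruth(f"{s.spacer_id}_copy{j}", s.start + off, s.end + off,
                              s.seq, s.source_contig, s.proto_start, s.proto_end,
                              s.mismatches) for s in a.spacers]
            t.arrays.append(ArrayTruth(f"{a.array_id}_copy{j}", a.contig_id,
                                       a.start + off, a.end + off, a.repeat,
                                       a.n_repeats, sp))
        for p in protos:
            t.protospacers.append(ProtospacerTruth(
                f"{p.spacer_id}_copy{j}", p.start + off, p.end + off, p.mismatches))


def _plant_array(factory: _SeqFactory, owner: str, ai: int, aspec: ArraySpec,
                 seqs: dict, truths: dict, occupied: dict,
                 proto_start: int | None = None) -> ArrayTruth:
    rng = factory.rng
    repeat = aspec.repeat_seq or factory.letters(
        aspec.repeat_len, truths[owner].gc_content, 0.0)
    n_spacers = aspec.n_repeats - 1
    if n_spacers < 1:
        raise SpecValidationError(f"{owner}: planted_arrays n_repeats must be >= 2")
    sources = list(aspec.spacer_sources) + ["random"] * (n_spacers - len(aspec.spacer_sources))
    if len(sources) > n_spacers:
        raise SpecValidationError(
            f"{owner}: planted_arrays has more spacer_sources than spacers")
    array_id = f"{owner}_arr{ai + 1}"
    spacer_info = []
    spacer_seqs = []
    for si, src in enumerate(sources):
        sid = f"{array_id}_sp{si + 1}"
        if src == "random" or src is None:
            sp = factory.letters(aspec.spacer_len, truths[owner].gc_content, 0.0)
            spacer_info.append((sid, sp, None, None, None))
        else:
            target, mm = src
            if target not in seqs:
                raise SpecValidationError(
                    f"{owner}: spacer_sources target {target!r} does not exist")
            if not 0 <= mm <= 3:
                raise SpecValidationError(
                    f"{owner}: spacer mismatches must be in 0..3, got {mm}")
            if proto_start is not None:
                ps = proto_start
                if _overlaps(ps, ps + aspec.spacer_len, occupied[target]):
                    raise FeatureCollisionError(
                        f"protospacer at {ps} on {target} collides with a planted feature")
                occupied[target].append((ps, ps + aspec.spacer_len))
            else:
                ps = _alloc(rng, len(seqs[target]), aspec.spacer_len,
                            occupied[target], _MARGIN, f"{sid} protospacer")
            proto = seqs[target][ps: ps + aspec.spacer_len]
            sp = _mutate(rng, proto, mm)
            truths[target].protospacers.append(
                ProtospacerTruth(sid, ps, ps + aspec.spacer_len, mm))
            spacer_info.append((sid, sp, target, ps, mm))
        spacer_seqs.append(spacer_info[-1][1])
    arr_seq = _array_sequence(repeat, spacer_seqs)
    start = _alloc(rng, len(seqs[owner]), len(arr_seq), occupied[owner],
                   max(_MARGIN, truths[owner].terminal_overlap + 100),
                   f"{array_id}")
    seqs[owner] = seqs[owner][:start] + arr_seq + seqs[owner][start + len(arr_seq):]
    spacers = []
    pos = start + len(repeat)
    for (sid, sp, target, ps, mm) in spacer_info:
        spacers.append(SpacerTruth(sid, pos, pos + len(sp), sp, target,
                                   ps, None if ps is None else ps + len(sp), mm))
        pos += len(sp) + len(repeat)
    at = ArrayTruth(array_id, owner, start, start + len(arr_seq), repeat,
                    aspec.n_repeats, spacers)
    truths[owner].arrays.append(at)
    return at


def plant_crispr_link(owner: ContigRecord, target: ContigRecord,
                      truth: PlantedTruth, n_spacers: int = 1,
                      mismatches=0, seed: int = 0, repeat_len: int = 32,
                      spacer_len: int = 34, proto_start: int | None = None):
    """Plant a CRISPR link: a new array on ``owner`` whose spacers have
    protospacers in ``target`` with exactly the requested mismatch counts.

    ``mismatches`` may be a single count or one per spacer (each <= 3).
    Returns updated ``(owner, target, truth)``; the target sequence is
    never modified, only its truth gains protospacer records. Raises
    :class:`FeatureCollisionError` if an explicitly requested
    ``proto_start`` collides with an already planted feature.
    """
    mms = [mismatches] * n_spacers if np.isscalar(mismatches) else list(mismatches)
    if len(mms) != n_spacers:
        raise SpecValidationError("mismatches: need one count per spacer")
    rng = np.random.default_rng(seed)
    factory = _SeqFactory(rng)
    seqs = {owner.id: owner.seq, target.id: target.seq}
    truths = truth.contigs
    for cid in (owner.id, target.id):
        if cid not in truths:
            raise SpecValidationError(f"truth ledger has no contig {cid!r}")
    occupied = {}
    for cid, t in ((owner.id, truths[owner.id]), (target.id, truths[target.id])):
        occ = [(a.start, a.end) for a in t.arrays]
        occ += [(p.start, p.end) for p in t.protospacers]
        m = max(_MARGIN, t.terminal_overlap + 100)
        occ += [(0, m), (len(seqs[cid]) - m, len(seqs[cid]))]
        occupied[cid] = occ
    aspec = ArraySpec(repeat_len=repeat_len, n_repeats=n_spacers + 1,
                      spacer_len=spacer_len,
                      spacer_sources=[(target.id, m) for m in mms])
    _plant_array(factory, owner.id, len(truths[owner.id].arrays), aspec,
                 seqs, truths, occupied, proto_start=proto_start)
    new_owner = ContigRecord(owner.id, seqs[owner.id], owner.source)
    truths[owner.id].length = len(seqs[owner.id])
    return new_owner, target, truth


def generate_genome(gspec: GenomeSpec, seed: int = 0):
    """Generate a single genome (convenience wrapper around
    :func:`generate_community`); returns (contig, annotations, truth)."""
    contigs, ann, truth = generate_community(
        CommunitySpec(seed=seed, genomes=[gspec]))
    return contigs[0], ann, truth.contigs[gspec.name]


# ---------------------------------------------------------------------------
# Protein-similarity tables (two-step family clustering input)
# ---------------------------------------------------------------------------

def simulate_protein_similarity(n_families: int = 4, subfams_per_family: int = 3,
                                proteins_per_subfam: int = 4, seed: int = 0,
                                within_cov: float = 0.9, within_prob: float = 98.0,
                                between_cov: float = 0.3, between_prob: float = 50.0):
    """Similarity tables with a planted two-level family structure.

    Proteins within a subfamily form a clique of strong all-vs-all edges
    (E-value 1e-30, coverage ``within_cov``); subfamilies of the same
    family are linked by profile edges of probability ``within_prob`` and
    coverage ``within_cov``; subfamilies of different families get weak
    profile edges (``between_prob``, ``between_cov``) that fall below the
    clustering thresholds. Returns ``(proteins, protein_edges,
    profile_edges, truth)`` where truth maps family index -> protein list
    and edge tables are DataFrames with columns
    query/target/evalue/coverage/probability.
    """
    rng = np.random.default_rng(seed)
    proteins = []
    subfam_members: dict[str, list] = {}
    truth: dict[int, list] = {}
    for f in range(n_families):
        truth[f] = []
        for s in range(subfams_per_family):
            sid = f"fam{f + 1:02d}_sub{s + 1:02d}"
            members = [f"{sid}_p{i + 1:02d}" for i in range(proteins_per_subfam)]
            subfam_members[sid] = members
            proteins.extend(members)
            truth[f].extend(members)
    prot_rows = []
    for sid, members in subfam_members.items():
        for i, a in enumerate(members):
            for b in members[i + 1:]:
                prot_rows.append({"query": a, "target": b, "evalue": 1e-30,
                                  "coverage": round(within_cov + rng.uniform(-0.05, 0.05), 3),
                                  "probability": np.nan})
    reps = {sid: min(m) for sid, m in subfam_members.items()}
    prof_rows = []
    sids = sorted(subfam_members)
    for i, s1 in enumerate(sids):
        for s2 in sids[i + 1:]:
            same = s1.split("_")[0] == s2.split("_")[0]
            cov = within_cov if same else between_cov
            prob = within_prob if same else between_prob
            prof_rows.append({"query": reps[s1], "target": reps[s2],
                              "evalue": np.nan,
                              "coverage": round(cov + rng.uniform(-0.03, 0.03), 3),
                              "probability": round(prob + rng.uniform(-1.0, 1.0), 1)})
    cols = ["query", "target", "evalue", "coverage", "probability"]
    return (proteins, pd.DataFrame(prot_rows, columns=cols),
            pd.DataFrame(prof_rows, columns=cols),
            {f: sorted(m) for f, m in truth.items()})


# ---------------------------------------------------------------------------
# tRNA-count table (genome size vs tRNA content statistic)
# ---------------------------------------------------------------------------

def simulate_trna_table(n: int = 200, rho: float = 0.6,
                        seed: int = 0) -> pd.DataFrame:
    """Genome-size / tRNA-count table with a planted Spearman correlation.

    Uses a Gaussian copula: the normal correlation is chosen as
    ``2*sin(pi*rho/6)`` so the rank correlation of the transformed pair is
    approximately ``rho``. Sizes span 200–700 kb; counts are small
    integers, mimicking tRNA inventories of huge phages.
    """
    from scipy.stats import norm

    rng = np.random.default_rng(seed)
    r = 2.0 * np.sin(np.pi * rho / 6.0)
    cov = np.array([[1.0, r], [r, 1.0]])
    z = rng.multivariate_normal([0.0, 0.0], cov, size=n)
    u = norm.cdf(z)
    sizes = (200_000 + 500_000 * u[:, 0]).astype(int)
    counts = np.round(66 * u[:, 1]).astype(int)
    return pd.DataFrame({"genome_id": [f"g{i + 1:04d}" for i in range(n)],
                         "length": sizes, "trna_count": counts})
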