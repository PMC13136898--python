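"""Self-contained toy datasets with ground-truth manifests.

The default fixture builds two small chromosomes carrying eleven genes that
together embed every supported AS class (RI, SE, A5, A3, AF, AL, MX) on both
strands, three special retained introns (an 81-nt stop-free in-frame case, an
early-stop case, a frameshift case), a 5'-UTR retained intron, and two genes
sharing a 10-codon block (a multi-gene peptide).  Everything is derived from
a single integer seed and regenerating with the same seed is byte-identical.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .genome_model import (
    GenomeSequence,
    Interval,
    TranscriptModel,
    reverse_complement,
    translate_cds,
)

_STOPS = {"TAA", "TAG", "TGA"}
_BASES = "ACGT"
_SAFE_CODONS = sorted(
    a + b + c
    for a in _BASES
    for b in _BASES
    for c in _BASES
    if a + b + c not in _STOPS
)

#: 3'UTR filler containing a stop codon in every reading frame
_UTR3 = ("TTAA" * 8)[:30]


def _rand_nt(rng: random.Random, n: int) -> str:
    return "".join(rng.choice(_BASES) for _ in range(n))


def _codons(rng: random.Random, n: int) -> str:
    return "".join(rng.choice(_SAFE_CODONS) for _ in range(n))


def _codons_dual_frame(rng: random.Random, n: int, shift: int) -> str:
    """n safe codons whose +shift frame is also stop-free (rejection sampled)."""
    while True:
        s = _codons(rng, n)
        if not any(s[i : i + 3] in _STOPS for i in range(shift, len(s) - 2, 3)):
            return s


@dataclass
class _Iso:
    suffix: int
    exons: list[Interval]  # locus coordinates, sense orientation
    cds: list[Interval]


@dataclass
class _Locus:
    gene_id: str
    strand: str
    seq: str
    isos: list[_Iso]
    events: list[dict] = field(default_factory=list)  # locus-coord truth
    special_introns: list[dict] = field(default_factory=list)


# ---------------------------------------------------------------------------
# gene builders (locus coordinates; sense orientation = transcript orientation)
# ---------------------------------------------------------------------------


def _gene_ri_inframe(rng: random.Random, gid: str, strand: str) -> _Locus:
    u5, c2, c3 = _rand_nt(rng, 30), _codons(rng, 40), _codons(rng, 20)
    c1 = "ATG" + _codons(rng, 29)
    i1 = "GTT" + _codons(rng, 25) + "CAG"  # 81 nt, in frame, stop-free
    i2 = "GT" + _rand_nt(rng, 86) + "AG"
    seq = u5 + c1 + i1 + c2 + i2 + c3 + "TAA" + _UTR3
    e1, iv1, e2, iv2, e3 = (0, 120), (120, 201), (201, 321), (321, 411), (411, 504)
    isos = [
        _Iso(1, [e1, e2, e3], [(30, 120), (201, 321), (411, 474)]),
        _Iso(2, [(0, 321), e3], [(30, 321), (411, 474)]),
    ]
    events = [dict(type="RI", disc=[iv1], incl=[2], excl=[1], region="CDS")]
    specials = [dict(interval=iv1, kind="inframe81", annotated=True, index=1)]
    return _Locus(gid, strand, seq, isos, events, specials)


def _gene_ri_earlystop(rng: random.Random, gid: str, strand: str) -> _Locus:
    u5, c2 = _rand_nt(rng, 30), _codons(rng, 30)
    c1 = "ATG" + _codons(rng, 29)
    i1 = "GTTGCTGCAGCCTAA" + _codons(rng, 19) + "CAG"  # 75 nt, stop at codon 5
    seq = u5 + c1 + i1 + c2 + "TGA" + _UTR3
    e1, iv1, e2 = (0, 120), (120, 195), (195, 318)
    isos = [
        _Iso(1, [e1, e2], [(30, 120), (195, 288)]),
        _Iso(2, [(0, 318)], [(30, 135)]),  # CDS ends at the intronic stop
    ]
    events = [dict(type="RI", disc=[iv1], incl=[2], excl=[1], region="CDS")]
    specials = [dict(interval=iv1, kind="earlystop", annotated=True, index=1)]
    return _Locus(gid, strand, seq, isos, events, specials)


def _gene_se(rng: random.Random, gid: str, strand: str) -> _Locus:
    u5, cB, cC = _rand_nt(rng, 30), _codons(rng, 12), _codons(rng, 27)
    cA = "ATG" + _codons(rng, 27)
    i1 = "GTTGCTTAA" + _rand_nt(rng, 59) + "AG"  # 70 nt, early stop when retained
    i2 = "GT" + _rand_nt(rng, 76) + "AG"
    seq = u5 + cA + i1 + cB + i2 + cC + "TAA" + _UTR3
    e1, iv1, e2, iv2, e3 = (0, 114), (114, 184), (184, 220), (220, 300), (300, 414)
    isos = [
        _Iso(1, [e1, e2, e3], [(30, 114), (184, 220), (300, 384)]),
        _Iso(2, [e1, e3], [(30, 114), (300, 384)]),
    ]
    events = [dict(type="SE", disc=[e2], incl=[1], excl=[2], region="CDS")]
    specials = [dict(interval=iv1, kind="earlystop_unannotated", annotated=False, index=1)]
    return _Locus(gid, strand, seq, isos, events, specials)


def _gene_a3(rng: random.Random, gid: str, strand: str) -> _Locus:
    u5, c2 = _rand_nt(rng, 30), _codons(rng, 20)
    c1 = "ATG" + _codons(rng, 30)
    i1 = "GT" + _rand_nt(rng, 77) + "AGCAG"  # both acceptors end in AG; extra codon CAG
    seq = u5 + c1 + i1 + c2 + "TAA" + _UTR3
    e1 = (0, 123)
    isos = [
        _Iso(1, [e1, (207, 300)], [(30, 123), (207, 270)]),
        _Iso(2, [e1, (204, 300)], [(30, 123), (204, 270)]),  # +1 Q
    ]
    events = [dict(type="A3" if strand == "+" else "A5", disc=[(204, 207)], incl=[2], excl=[1], region="CDS")]
    return _Locus(gid, strand, seq, isos, events, [])


def _gene_a5_minus(rng: random.Random, gid: str) -> _Locus:
    """Alternative transcript-5' splice site; placed on the minus strand."""
    u5, c2 = _rand_nt(rng, 30), _codons(rng, 21)
    c1 = "ATG" + _codons(rng, 29)
    # locus[120:126] = two extra codons of iso2 (also iso1's donor "GT...")
    extra = "GTCGAA"
    i_body = "GT" + _rand_nt(rng, 80) + "AG"  # iso2 intron (126,210)
    seq = u5 + c1 + extra + i_body + c2 + "TGA" + _UTR3
    isos = [
        _Iso(1, [(0, 120), (210, 306)], [(30, 120), (210, 276)]),
        _Iso(2, [(0, 126), (210, 306)], [(30, 126), (210, 276)]),
    ]
    # minus strand: the variation is at the transcripts' 5' splice site
    events = [dict(type="A5", disc=[(120, 126)], incl=[2], excl=[1], region="CDS")]
    return _Locus(gid, "-", seq, isos, events, [])


def _gene_af(rng: random.Random, gid: str, strand: str) -> _Locus:
    a1 = _rand_nt(rng, 30) + "ATG" + _codons(rng, 14)  # (0,75)
    a2 = _rand_nt(rng, 24) + "ATG" + _codons(rng, 14)  # (150,219)
    e2c, e3c = _codons(rng, 30), _codons(rng, 20)
    seq = (
        a1
        + "GT"
        + _rand_nt(rng, 73)
        + a2
        + "GT"
        + _rand_nt(rng, 77)
        + "AG"
        + e2c
        + "GT"
        + _rand_nt(rng, 66)
        + "AG"
        + e3c
        + "TAA"
        + _UTR3
    )
    A1, A2, E2, E3 = (0, 75), (150, 219), (300, 390), (460, 553)
    isos = [
        _Iso(1, [A1, E2, E3], [(30, 75), (300, 390), (460, 523)]),
        _Iso(2, [A2, E2, E3], [(174, 219), (300, 390), (460, 523)]),
    ]
    events = [
        dict(type="AF", disc=[A1], excl_region=[A2], incl=[1], excl=[2], region="CDS")
    ]
    return _Locus(gid, strand, seq, isos, events, [])


def _gene_al_minus(rng: random.Random, gid: str) -> _Locus:
    e1c, e2c = "ATG" + _codons(rng, 24), _codons(rng, 30)
    l1 = _codons(rng, 15) + "TAA" + _UTR3  # 78 nt at (340,418)
    l2 = _codons(rng, 10) + "TGA" + _UTR3  # 63 nt at (470,533)
    seq = (
        _rand_nt(rng, 30)
        + e1c
        + "GT"
        + _rand_nt(rng, 76)
        + "AG"
        + e2c
        + "GT"
        + _rand_nt(rng, 61)
        + "AG"
        + l1
        + _rand_nt(rng, 50)
        + "AG"
        + l2
    )
    E1, E2, L1, L2 = (0, 105), (185, 275), (340, 418), (470, 533)
    isos = [
        _Iso(1, [E1, E2, L1], [(30, 105), (185, 275), (340, 388)]),
        _Iso(2, [E1, E2, L2], [(30, 105), (185, 275), (470, 503)]),
    ]
    # transcript-3'-most distal last exon (L2) is the inclusion form
    events = [
        dict(type="AL", disc=[L2], excl_region=[L1], incl=[2], excl=[1], region="CDS")
    ]
    return _Locus(gid, "-", seq, isos, events, [])


def _gene_mx(rng: random.Random, gid: str, strand: str) -> _Locus:
    e1c, bc, cc, e4c = "ATG" + _codons(rng, 19), _codons(rng, 17), _codons(rng, 22), _codons(rng, 15)
    seq = (
        _rand_nt(rng, 30)
        + e1c
        + "GT"
        + _rand_nt(rng, 76)
        + "AG"
        + bc
        + "GT"
        + _rand_nt(rng, 76)
        + "AG"
        + cc
        + "GT"
        + _rand_nt(rng, 76)
        + "AG"
        + e4c
        + "TAA"
        + _UTR3
    )
    E1, B, C, E4 = (0, 90), (170, 221), (301, 367), (447, 525)
    isos = [
        _Iso(1, [E1, B, E4], [(30, 90), (170, 221), (447, 495)]),
        _Iso(2, [E1, C, E4], [(30, 90), (301, 367), (447, 495)]),
    ]
    events = [
        dict(type="MX", disc=[B], excl_region=[C], incl=[1], excl=[2], region="CDS")
    ]
    return _Locus(gid, strand, seq, isos, events, [])


def _gene_single_frameshift(
    rng: random.Random, gid: str, shared30: str, strand: str
) -> _Locus:
    """Single-isoform gene whose 80-nt intron shifts the frame when retained.

    The retained reading frame runs through exon 2 at a +1 offset and is kept
    stop-free until a planted TGA at exon-2 offset 76, so the IR protein is a
    deterministic frameshift extension.
    """
    u5, c1 = _rand_nt(rng, 30), "ATG" + _codons(rng, 29)
    i1 = "GTT" + _codons(rng, 25) + "AG"  # 80 nt -> +1 frame offset downstream
    while True:
        tail_a = _codons(rng, 15)  # exon-2 offsets 30..74
        tail_b = _codons(rng, 3)  # offsets 81..89 (after the shifted stop)
        c2 = shared30 + tail_a + "CTGAAA" + tail_b  # TGA at offset 76 in +1 frame
        assert len(c2) == 90 and c2[76:79] == "TGA"
        if not any(c2[i : i + 3] in _STOPS for i in range(1, 76, 3)):
            break
    seq = u5 + c1 + i1 + c2 + "TAA" + _UTR3
    isos = [_Iso(1, [(0, 120), (200, 323)], [(30, 120), (200, 293)])]
    specials = [dict(interval=(120, 200), kind="frameshift", annotated=False, index=1)]
    return _Locus(gid, strand, seq, isos, [], specials)


def _gene_utr5_ri(rng: random.Random, gid: str, strand: str) -> _Locus:
    seq = (
        _rand_nt(rng, 30)
        + "GT"
        + _rand_nt(rng, 56)
        + "AG"
        + _rand_nt(rng, 10)
        + "ATG"
        + _codons(rng, 39)
        + "TAA"
        + _UTR3
    )
    cds = [(100, 223)]
    isos = [
        _Iso(1, [(0, 30), (90, 263)], list(cds)),
        _Iso(2, [(0, 263)], list(cds)),
    ]
    events = [dict(type="RI", disc=[(30, 90)], incl=[2], excl=[1], region="UTR")]
    specials = [dict(interval=(30, 90), kind="utr5", annotated=True, index=1)]
    return _Locus(gid, strand, seq, isos, events, specials)


def _gene_utr3_intron(
    rng: random.Random, gid: str, shared30: str, strand: str
) -> _Locus:
    cds_nt = "ATG" + _codons(rng, 9) + shared30 + _codons(rng, 20)
    seq = (
        _rand_nt(rng, 30)
        + cds_nt
        + "TAA"
        + _rand_nt(rng, 10)
        + "GT"
        + _rand_nt(rng, 62)
        + "AG"
        + _rand_nt(rng, 40)
    )
    isos = [_Iso(1, [(0, 163), (229, 269)], [(30, 153)])]
    specials = [dict(interval=(163, 229), kind="utr3", annotated=False, index=1)]
    return _Locus(gid, strand, seq, isos, [], specials)


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------


@dataclass
class FixtureSpec:
    """Knobs of the default fixture."""

    spacer: int = 200
    exon_baseline_depth: float = 100.0
    noise_sd: float = 0.0
    wt_samples: tuple[str, ...] = ("wt1", "wt2", "wt3", "wt4", "wt5")
    mut_samples: tuple[str, ...] = ("mut1", "mut2", "mut3", "mut4", "mut5")
    decoy_tag: str = "DECOY_"
    #: target IDratio per (gene_id, first-isoform plus-strand intron index)
    idratio_targets: dict = field(
        default_factory=lambda: {
            ("AT1G00010", 1): {"WT": 0.40, "mut": 0.50},
            ("AT1G00020", 1): {"WT": 0.10, "mut": 0.30},
            ("AT1G00030", 1): {"WT": 0.02, "mut": 0.20},
            ("AT2G00040", 1): {"WT": 0.30, "mut": 0.35},
            ("AT2G00050", 1): {"WT": 0.05, "mut": 0.40},
            ("AT2G00060", 1): {"WT": 0.05, "mut": 0.30},
        }
    )
    default_idratio: float = 0.01


@dataclass
class FixtureManifest:
    seed: int
    genes: dict
    events: list
    peptides: list
    event_support: list
    ir: dict
    iir: list
    files: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "FixtureManifest":
        with open(path) as fh:
            return cls(**json.load(fh))


def _flip(iv: Interval, length: int) -> Interval:
    return (length - iv[1], length - iv[0])


def _build_loci(rng: random.Random) -> list[tuple[str, _Locus]]:
    # shared block must stay stop-free in the +1 frame of the frameshift gene
    shared30 = _codons_dual_frame(rng, 10, shift=1)
    return [
        ("Chr1", _gene_ri_inframe(rng, "AT1G00010", "+")),
        ("Chr1", _gene_ri_earlystop(rng, "AT1G00020", "-")),
        ("Chr1", _gene_se(rng, "AT1G00030", "+")),
        ("Chr1", _gene_a3(rng, "AT1G00040", "+")),
        ("Chr1", _gene_a5_minus(rng, "AT1G00050")),
        ("Chr2", _gene_af(rng, "AT2G00010", "+")),
        ("Chr2", _gene_al_minus(rng, "AT2G00020")),
        ("Chr2", _gene_mx(rng, "AT2G00030", "+")),
        ("Chr2", _gene_single_frameshift(rng, "AT2G00040", shared30, "+")),
        ("Chr2", _gene_utr5_ri(rng, "AT2G00050", "+")),
        ("Chr2", _gene_utr3_intron(rng, "AT2G00060", shared30, "+")),
    ]


@dataclass
class Fixture:
    """In-memory fixture: genome, transcript models, manifest, truth helpers."""

    genome: dict[str, GenomeSequence]
    transcripts: list[TranscriptModel]
    manifest: FixtureManifest
    spec: FixtureSpec


def build_fixture(seed: int = 0, spec: FixtureSpec | None = None) -> Fixture:
    spec = spec or FixtureSpec()
    rng = random.Random(seed)
    placed = _build_loci(rng)

    chrom_seq: dict[str, str] = {}
    transcripts: list[TranscriptModel] = []
    genes_meta: dict = {}
    events_truth: list = []
    specials: list = []

    for chrom, locus in placed:
        prefix = chrom_seq.get(chrom, "")
        offset = len(prefix) + spec.spacer
        L = len(locus.seq)
        if locus.strand == "+":
            genomic_seq = locus.seq
            conv = lambda iv: (offset + iv[0], offset + iv[1])  # noqa: E731
        else:
            genomic_seq = reverse_complement(locus.seq)
            conv = lambda iv: (offset + L - iv[1], offset + L - iv[0])  # noqa: E731
        chrom_seq[chrom] = prefix + _rand_nt(rng, spec.spacer) + genomic_seq

        iso_meta = {}
        for iso in locus.isos:
            tid = f"{locus.gene_id}.{iso.suffix}"
            exons = tuple(sorted(conv(iv) for iv in iso.exons))
            cds = tuple(sorted(conv(iv) for iv in iso.cds))
            nt = "".join(locus.seq[s:e] for s, e in sorted(iso.cds))
            protein = translate_cds(nt, "+")  # locus coords are sense
            transcripts.append(
                TranscriptModel(
                    transcript_id=tid,
                    gene_id=locus.gene_id,
                    chrom=chrom,
                    strand=locus.strand,
                    exons=exons,
                    cds_segments=cds,
                    protein_sequence=protein,
                )
            )
            iso_meta[tid] = {"exons": [list(e) for e in exons], "cds": [list(c) for c in cds]}
        genes_meta[locus.gene_id] = {
            "chrom": chrom,
            "strand": locus.strand,
            "isoforms": iso_meta,
        }
        for ev in locus.events:
            events_truth.append(
                {
                    "gene_id": locus.gene_id,
                    "type": ev["type"],
                    "disc": [list(conv(tuple(iv))) for iv in ev["disc"]],
                    "inclusion": sorted(f"{locus.gene_id}.{s}" for s in ev["incl"]),
                    "exclusion": sorted(f"{locus.gene_id}.{s}" for s in ev["excl"]),
                    "region": ev["region"],
                }
            )
        for sp in locus.special_introns:
            specials.append(
                {
                    "gene_id": locus.gene_id,
                    "chrom": chrom,
                    "strand": locus.strand,
                    "interval": list(conv(tuple(sp["interval"]))),
                    "kind": sp["kind"],
                    "annotated": sp["annotated"],
                    "plus_strand_index": _plus_index(locus, sp["interval"]),
                }
            )

    genome = {c: GenomeSequence(c, s) for c, s in chrom_seq.items()}
    peptides, support = _plant_peptides(transcripts)
    ir_truth, iir_truth = _depth_truth(transcripts, genome, specials, spec)
    manifest = FixtureManifest(
        seed=seed,
        genes=genes_meta,
        events=events_truth,
        peptides=peptides,
        event_support=support,
        ir=ir_truth,
        iir=iir_truth,
    )
    return Fixture(genome=genome, transcripts=transcripts, manifest=manifest, spec=spec)


def _plus_index(locus: _Locus, interval_locus: Interval) -> int:
    """Plus-strand index of a first-isoform intron given in locus coords."""
    iso1 = locus.isos[0]
    locus_introns = [
        (iso1.exons[i][1], iso1.exons[i + 1][0]) for i in range(len(iso1.exons) - 1)
    ]
    n = len(locus_introns)
    locus_idx = locus_introns.index(tuple(interval_locus)) + 1
    return locus_idx if locus.strand == "+" else n - locus_idx + 1


# ---------------------------------------------------------------------------
# planted peptides
# ---------------------------------------------------------------------------

#: (gene, iso suffix, 1-based residue interval, role, engines)
_PLANT_PLAN: list[tuple[str, int, int, int, str, tuple[str, ...]]] = [
    ("AT1G00010", 1, 5, 13, "shared", ("prospector",)),
    ("AT1G00010", 1, 28, 34, "excl", ("prospector",)),
    ("AT1G00010", 2, 28, 37, "incl", ("prospector",)),
    ("AT1G00020", 1, 3, 11, "shared", ("prospector",)),
    ("AT1G00020", 1, 28, 34, "excl", ("prospector",)),
    ("AT1G00020", 2, 27, 34, "incl", ("prospector",)),
    ("AT1G00030", 1, 3, 11, "shared", ("prospector",)),
    ("AT1G00030", 1, 26, 33, "incl", ("prospector",)),
    ("AT1G00030", 1, 30, 38, "specific_extra", ("prospector",)),
    ("AT1G00030", 2, 26, 33, "excl", ("prospector",)),
    ("AT1G00040", 1, 5, 13, "shared", ("prospector",)),
    ("AT1G00040", 2, 29, 36, "incl", ("prospector", "fragger")),
    ("AT1G00040", 1, 29, 35, "excl", ("prospector", "fragger")),
    ("AT1G00050", 1, 5, 13, "shared", ("prospector",)),
    ("AT1G00050", 2, 29, 36, "incl", ("prospector", "fragger")),
    ("AT1G00050", 1, 28, 34, "excl", ("prospector", "fragger")),
    ("AT2G00010", 1, 20, 28, "shared", ("fragger",)),
    ("AT2G00010", 1, 4, 12, "incl", ("fragger",)),
    ("AT2G00010", 2, 4, 12, "excl", ("fragger",)),
    ("AT2G00020", 1, 10, 18, "shared", ("fragger",)),
    ("AT2G00020", 2, 57, 64, "incl", ("fragger",)),
    ("AT2G00020", 1, 58, 66, "excl", ("fragger",)),
    ("AT2G00030", 1, 3, 11, "shared", ("fragger",)),
    ("AT2G00030", 1, 18, 25, "incl", ("fragger",)),
    ("AT2G00030", 2, 18, 25, "excl", ("fragger",)),
    ("AT2G00040", 1, 45, 53, "single", ("fragger",)),
    ("AT2G00040", 1, 2, 11, "met_loss", ("fragger",)),
    ("AT2G00040", 1, 31, 40, "multi_gene", ("fragger",)),
    ("AT2G00050", 1, 5, 13, "shared", ("prospector",)),
    ("AT2G00060", 1, 25, 33, "single", ("fragger",)),
]

_ROLE_CATEGORY = {
    "shared": "shared_all_isoforms",
    "incl": "isoform_specific",
    "excl": "isoform_specific",
    "specific_extra": "isoform_specific",
    "single": "single_isoform_gene",
    "met_loss": "single_isoform_gene",
    "multi_gene": "multi_gene",
}

#: event-support truth per gene: role -> (form, evidence)
_SUPPORT_EVIDENCE = {
    "AT1G00010": {"incl": "overlap", "excl": "junction"},
    "AT1G00020": {"incl": "overlap", "excl": "junction"},
    "AT1G00030": {"incl": "junction", "excl": "junction"},
    "AT1G00040": {"incl": "overlap", "excl": "junction"},
    "AT1G00050": {"incl": "overlap", "excl": "junction"},
    "AT2G00010": {"incl": "overlap", "excl": "overlap"},
    "AT2G00020": {"incl": "overlap", "excl": "overlap"},
    "AT2G00030": {"incl": "junction", "excl": "junction"},
}


def _plant_peptides(transcripts: Sequence[TranscriptModel]) -> tuple[list, list]:
    by_id = {t.transcript_id: t for t in transcripts}
    proteins = {t.transcript_id: t.protein_sequence for t in transcripts if t.protein_sequence}
    peptides = []
    support: dict[tuple[str, str], dict] = {}
    seen: set[str] = set()
    for gene, suffix, r1, r2, role, engines in _PLANT_PLAN:
        tid = f"{gene}.{suffix}"
        prot = proteins[tid]
        seq = prot[r1 - 1 : r2]
        if len(seq) != r2 - r1 + 1:
            raise RuntimeError(f"plant out of range: {tid} {r1}-{r2}")
        matched = sorted(a for a, p in proteins.items() if seq in p)
        expected = _expected_match_set(gene, suffix, role, proteins)
        if set(matched) != expected:
            raise RuntimeError(
                f"fixture collision: peptide {seq} ({tid} {role}) matched {matched}, "
                f"expected {sorted(expected)}"
            )
        if seq in seen:
            raise RuntimeError(f"duplicate planted peptide {seq}")
        seen.add(seq)
        peptides.append(
            {
                "sequence": seq,
                "category": _ROLE_CATEGORY[role],
                "role": role,
                "gene_id": gene,
                "source_transcript": tid,
                "protein_start": r1,
                "matched_isoforms": matched,
                "engines": sorted(engines),
                "met_loss": role == "met_loss",
            }
        )
        if role in ("incl", "excl"):
            form = "inclusion" if role == "incl" else "exclusion"
            key = (gene, form)
            support[key] = {
                "gene_id": gene,
                "form": form,
                "evidence": _SUPPORT_EVIDENCE[gene][role],
                "peptides": [seq],
            }
    return peptides, [support[k] for k in sorted(support)]


def _expected_match_set(
    gene: str, suffix: int, role: str, proteins: Mapping[str, str]
) -> set[str]:
    gene_isoforms = {a for a in proteins if a.startswith(gene + ".")}
    if role == "shared":
        return set(gene_isoforms)
    if role in ("incl", "excl", "specific_extra", "single", "met_loss"):
        return {f"{gene}.{suffix}"}
    if role == "multi_gene":
        return {"AT2G00040.1", "AT2G00060.1"}
    raise ValueError(role)


# ---------------------------------------------------------------------------
# depth / IR truth
# ---------------------------------------------------------------------------


def _iso1_intron_targets(
    transcripts: Sequence[TranscriptModel], spec: FixtureSpec
) -> dict[tuple[str, Interval], dict[str, float]]:
    """Map genomic intron intervals to target IDratios per group."""
    from .genome_model import enumerate_introns

    targets: dict[tuple[str, Interval], dict[str, float]] = {}
    for t in transcripts:
        if not t.transcript_id.endswith(".1"):
            continue
        for intron in enumerate_introns(t):
            key = (t.gene_id, intron.plus_strand_index)
            if key in spec.idratio_targets:
                targets[(t.chrom, intron.interval)] = spec.idratio_targets[key]
    return targets


def _ir_protein_oracle(
    t: TranscriptModel, iv: Interval, genome: Mapping[str, GenomeSequence]
) -> str:
    segs = sorted(list(t.cds_segments) + [tuple(iv)])
    nt = "".join(genome[t.chrom].fetch(s, e) for s, e in segs)
    return translate_cds(nt, t.strand)


def _depth_truth(
    transcripts: Sequence[TranscriptModel],
    genome: Mapping[str, GenomeSequence],
    specials: Sequence[dict],
    spec: FixtureSpec,
) -> tuple[dict, list]:
    by_id = {t.transcript_id: t for t in transcripts}
    region_by_kind = {
        "inframe81": "CDS",
        "earlystop": "CDS",
        "earlystop_unannotated": "CDS",
        "frameshift": "CDS",
        "utr5": "5UTR",
        "utr3": "3UTR",
    }
    entries: dict[str, dict] = {}
    annotated_entries: dict[str, dict] = {}
    candidates: list[dict] = []
    for sp in specials:
        gene = sp["gene_id"]
        tid = f"{gene}.1"
        t = by_id[tid]
        iv = tuple(sp["interval"])
        acc = f"{tid}_IR{sp['plus_strand_index']}"
        in_cds = any(
            t.cds_segments[i][1] == iv[0] and t.cds_segments[i + 1][0] == iv[1]
            for i in range(len(t.cds_segments) - 1)
        )
        if in_cds:
            protein = _ir_protein_oracle(t, iv, genome)
            delta = len(protein) - len(t.protein_sequence)
            if delta < 0:
                outcome = "truncated"
            elif (iv[1] - iv[0]) % 3 == 0 and delta == (iv[1] - iv[0]) // 3:
                outcome = "extended_in_frame"
            else:
                outcome = "frameshift_extended"
            entry = {
                "outcome": outcome,
                "delta": delta,
                "in_cds": True,
                "protein": protein,
            }
        else:
            entry = {
                "outcome": "extended_in_frame",
                "delta": 0,
                "in_cds": False,
                "protein": t.protein_sequence,
            }
        if sp["annotated"]:
            annotated_entries[acc] = entry
        else:
            targets = spec.idratio_targets.get((gene, sp["plus_strand_index"]), {})
            if any(v >= 0.15 for v in targets.values()):
                candidates.append(
                    {
                        "gene_id": gene,
                        "interval": list(iv),
                        "plus_strand_index": sp["plus_strand_index"],
                        "accession": acc,
                    }
                )
                entries[acc] = entry

    def _frac(d: dict) -> float | None:
        cds = [e for e in d.values() if e["in_cds"]]
        if not cds:
            return None
        return sum(1 for e in cds if e["outcome"] == "truncated") / len(cds)

    ir_truth = {
        "candidates": candidates,
        "entries": entries,
        "annotated_entries": annotated_entries,
        "truncated_fraction": {
            "annotated": _frac(annotated_entries),
            "unannotated": _frac(entries),
        },
    }

    iir_truth = []
    from .genome_model import enumerate_introns

    for sp in specials:
        gene = sp["gene_id"]
        targets = spec.idratio_targets.get((gene, sp["plus_strand_index"]))
        if targets is None:
            continue
        wt, mut = targets["WT"], targets["mut"]
        fold = mut / max(wt, 0.01)
        iir_truth.append(
            {
                "gene_id": gene,
                "interval": list(sp["interval"]),
                "region": region_by_kind[sp["kind"]],
                "wt": wt,
                "mut": mut,
                "fold": fold,
                "is_iir": mut >= 0.15 and fold >= 1.5,
            }
        )
    # targeted introns without a special role (e.g. the in-frame annotated RI)
    return ir_truth, iir_truth


# ---------------------------------------------------------------------------
# file writers
# ---------------------------------------------------------------------------


def write_genome_fasta(genome: Mapping[str, GenomeSequence], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(genome):
            fh.write(f">{chrom}\n")
            seq = genome[chrom].sequence
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def write_gff3(transcripts: Sequence[TranscriptModel], path: str | Path) -> None:
    from .genome_model import transcripts_by_gene

    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene_id, ts in sorted(transcripts_by_gene(transcripts).items()):
            chrom, strand = ts[0].chrom, ts[0].strand
            g_start = min(t.exons[0][0] for t in ts) + 1
            g_end = max(t.exons[-1][1] for t in ts)
            fh.write(
                f"{chrom}\tfixture\tgene\t{g_start}\t{g_end}\t.\t{strand}\t.\tID={gene_id}\n"
            )
            for t in ts:
                fh.write(
                    f"{chrom}\tfixture\tmRNA\t{t.exons[0][0] + 1}\t{t.exons[-1][1]}\t.\t"
                    f"{strand}\t.\tID={t.transcript_id};Parent={gene_id}\n"
                )
                for s, e in t.exons:
                    fh.write(
                        f"{chrom}\tfixture\texon\t{s + 1}\t{e}\t.\t{strand}\t.\t"
                        f"Parent={t.transcript_id}\n"
                    )
                for s, e in t.cds_segments:
                    fh.write(
                        f"{chrom}\tfixture\tCDS\t{s + 1}\t{e}\t.\t{strand}\t0\t"
                        f"Parent={t.transcript_id}\n"
                    )


# ---------------------------------------------------------------------------
# in-silico digestion
# ---------------------------------------------------------------------------


def digest(protein: str, enzyme: str, max_missed: int = 1) -> list[str]:
    """Cleave a protein: trypsin (after K/R, not before P) or AspN (before D).

    Returns peptides with up to ``max_missed`` missed cleavages, in N->C
    order (full-cleavage fragments first).
    """
    if enzyme == "trypsin":
        cuts = [
            i + 1
            for i in range(len(protein) - 1)
            if protein[i] in "KR" and protein[i + 1] != "P"
        ]
    elif enzyme == "aspn":
        cuts = [i for i in range(1, len(protein)) if protein[i] == "D"]
    else:
        raise ValueError(f"unknown enzyme {enzyme!r}")
    bounds = [0] + cuts + [len(protein)]
    frags = [protein[a:b] for a, b in zip(bounds, bounds[1:]) if b > a]
    out = list(frags)
    for miss in range(1, max_missed + 1):
        for i in range(len(frags) - miss):
            out.append("".join(frags[i : i + miss + 1]))
    return out


def digest_and_sample_peptides(
    fixture: Fixture,
    out_dir: str | Path,
    seed: int = 0,
    n_extra_digested: int = 4,
) -> dict[str, Path]:
    """Write the two engine-dialect peptide TSVs (planted + decoys + a few
    tryptic peptides from the single-isoform genes)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = random.Random(seed)
    proteins = {
        t.transcript_id: t.protein_sequence
        for t in fixture.transcripts
        if t.protein_sequence
    }
    planted = fixture.manifest.peptides
    planted_seqs = {p["sequence"] for p in planted}

    # extra tryptic peptides only from the single-isoform genes, so their
    # category is decidable without the disjointness rule
    extra_rows = []
    for tid in ("AT2G00040.1", "AT2G00060.1"):
        frags = sorted({f for f in digest(proteins[tid], "trypsin") if len(f) >= 6})
        rng.shuffle(frags)
        for seq in frags[: n_extra_digested // 2]:
            if seq in planted_seqs:
                continue
            matched = sorted(a for a, p in proteins.items() if seq in p)
            genes = sorted({a.rsplit(".", 1)[0] for a in matched})
            if not matched or any(
                g not in ("AT2G00040", "AT2G00060") for g in genes
            ):
                continue
            extra_rows.append((seq, matched))
            planted_seqs.add(seq)
            fixture.manifest.peptides.append(
                {
                    "sequence": seq,
                    "category": "multi_gene" if len(genes) > 1 else "single_isoform_gene",
                    "role": "digested",
                    "gene_id": genes[0],
                    "source_transcript": tid,
                    "protein_start": proteins[tid].find(seq) + 1,
                    "matched_isoforms": matched,
                    "engines": ["fragger"],
                    "met_loss": False,
                }
            )

    decoys = []
    for p in planted[:3]:
        decoys.append(
            (p["sequence"][::-1], [f"{fixture.spec.decoy_tag}{p['matched_isoforms'][0]}"])
        )

    pros_path = out_dir / "peptides_prospector.tsv"
    frag_path = out_dir / "peptides_fragger.tsv"
    with open(pros_path, "w") as fh:
        fh.write("DB Peptide\tAcc #\n")
        for p in planted:
            if "prospector" not in p["engines"]:
                continue
            seq = p["sequence"]
            if p["role"] == "shared" and p["gene_id"] == "AT1G00010":
                seq = seq[0] + "(ox)" + seq[1:]  # exercise modification stripping
            fh.write(f"{seq}\t{';'.join(p['matched_isoforms'])}\n")
        for seq, accs in decoys:
            fh.write(f"{seq}\t{';'.join(accs)}\n")
    with open(frag_path, "w") as fh:
        fh.write("Peptide\tProtein\n")
        for p in planted:
            if "fragger" not in p["engines"]:
                continue
            fh.write(f"{p['sequence']}\t{','.join(p['matched_isoforms'])}\n")
        for seq, accs in extra_rows:
            fh.write(f"{seq}\t{','.join(accs)}\n")
    return {"prospector": pros_path, "fragger": frag_path}


def make_coverage(
    fixture: Fixture,
    out_path: str | Path,
    seed: int = 0,
    noise_sd: float | None = None,
) -> Path:
    """Region-depth TSV over every exon/intron interval of every transcript.

    Exon depths sit at the baseline; intron depths are target-IDratio x
    baseline, with optional multiplicative Gaussian noise.
    """
    from .genome_model import enumerate_introns

    spec = fixture.spec
    noise = spec.noise_sd if noise_sd is None else noise_sd
    rng = random.Random(seed)
    targets = _iso1_intron_targets(fixture.transcripts, spec)

    exon_regions: set[tuple[str, Interval]] = set()
    intron_regions: set[tuple[str, Interval]] = set()
    for t in fixture.transcripts:
        for ex in t.exons:
            exon_regions.add((t.chrom, ex))
        for intron in enumerate_introns(t):
            intron_regions.add((t.chrom, intron.interval))

    samples = [("WT", s) for s in spec.wt_samples] + [
        ("mut", s) for s in spec.mut_samples
    ]

    def depth(base: float) -> float:
        return base * max(0.0, 1.0 + (rng.gauss(0.0, noise) if noise > 0 else 0.0))

    out_path = Path(out_path)
    with open(out_path, "w") as fh:
        fh.write("chrom\tstart\tend\tsample\tmean_depth\n")
        for chrom, iv in sorted(exon_regions):
            for _, sample in samples:
                fh.write(
                    f"{chrom}\t{iv[0]}\t{iv[1]}\t{sample}\t"
                    f"{depth(spec.exon_baseline_depth):.6g}\n"
                )
        for chrom, iv in sorted(intron_regions):
            tgt = targets.get((chrom, iv), {})
            for group, sample in samples:
                ratio = tgt.get(group, spec.default_idratio)
                fh.write(
                    f"{chrom}\t{iv[0]}\t{iv[1]}\t{sample}\t"
                    f"{depth(ratio * spec.exon_baseline_depth):.6g}\n"
                )
    return out_path


def make_genome_and_annotation(
    out_dir: str | Path,
    seed: int = 0,
    spec: FixtureSpec | None = None,
) -> Fixture:
    """Write the full fixture bundle (FASTA, GFF3, proteins, peptide TSVs,
    coverage TSV, manifest JSON) into ``out_dir`` and return the fixture."""
    from .genome_model import write_protein_fasta

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fx = build_fixture(seed=seed, spec=spec)
    write_genome_fasta(fx.genome, out_dir / "genome.fa")
    write_gff3(fx.transcripts, out_dir / "annotation.gff3")
    write_protein_fasta(fx.transcripts, out_dir / "proteins.fa")
    tables = digest_and_sample_peptides(fx, out_dir, seed=seed)
    cov = make_coverage(fx, out_dir / "coverage.tsv", seed=seed)
    fx.manifest.files = {
        "genome": "genome.fa",
        "annotation": "annotation.gff3",
        "proteins": "proteins.fa",
        "prospector": tables["prospector"].name,
        "fragger": tables["fragger"].name,
        "coverage": cov.name,
    }
    fx.manifest.to_json(out_dir / "manifest.json")
    return fx
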