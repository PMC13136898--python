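"""Transcript models: GFF3/FASTA ingestion, CDS translation, intron inventory.

Internal coordinates are 0-based half-open throughout the package; the GFF3
convention (1-based closed) is converted at the I/O boundary only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
from Bio import SeqIO
from Bio.Data import CodonTable

logger = logging.getLogger(__name__)

Interval = tuple[int, int]  # 0-based half-open

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]
_CODON_TO_AA: dict[str, str] = dict(_STANDARD_TABLE.forward_table)
STOP_CODONS = frozenset(_STANDARD_TABLE.stop_codons)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
VALID_NT = frozenset("ACGTN")


class AnnotationError(ValueError):
    """Raised when the annotation violates structural contracts."""


def reverse_complement(nt: str) -> str:
    return nt.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomeSequence:
    """One chromosome: an uppercase A/C/G/T/N string."""

    chrom_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for {self.chrom_id}")
        bad = set(self.sequence) - VALID_NT
        if bad:
            raise ValueError(f"invalid symbols in {self.chrom_id}: {sorted(bad)}")

    def fetch(self, start: int, end: int) -> str:
        """Plus-strand slice, 0-based half-open."""
        if not (0 <= start < end <= len(self.sequence)):
            raise ValueError(
                f"slice [{start},{end}) outside {self.chrom_id} "
                f"(length {len(self.sequence)})"
            )
        return self.sequence[start:end]


@dataclass(frozen=True)
class TranslationResult:
    protein: str
    stopped: bool  # hit an in-frame stop codon
    partial_codon: bool  # trailing 1-2 nt dropped


def translate_cds(nt: str, strand: str = "+") -> str:
    """Translate a CDS given in genomic plus-strand orientation.

    Minus-strand input is reverse-complemented first.  Translation stops at
    the first in-frame stop codon (not emitted); codons containing N yield
    'X'; a trailing partial codon is dropped.
    """
    return translate_cds_full(nt, strand).protein


def translate_cds_full(nt: str, strand: str = "+") -> TranslationResult:
    if strand not in ("+", "-"):
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    if not nt:
        raise ValueError("empty CDS")
    nt = nt.upper()
    bad = set(nt) - VALID_NT
    if bad:
        raise ValueError(f"invalid nucleotide symbols: {sorted(bad)}")
    if strand == "-":
        nt = reverse_complement(nt)
    aas: list[str] = []
    stopped = False
    for i in range(0, len(nt) - 2, 3):
        codon = nt[i : i + 3]
        if codon in STOP_CODONS:
            stopped = True
            break
        # spec contract: any N-containing codon is 'X', no ambiguity resolution
        aas.append(_CODON_TO_AA.get(codon, "X"))
    partial = (not stopped) and (len(nt) % 3 != 0)
    return TranslationResult("".join(aas), stopped, partial)


@dataclass(frozen=True)
class TranscriptModel:
    """Exon/CDS structure of one isoform with derived protein sequence.

    ``exons`` and ``cds_segments`` are ascending, non-overlapping genomic
    intervals (0-based half-open) regardless of strand.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[Interval, ...]
    cds_segments: tuple[Interval, ...] = ()
    protein_sequence: str = ""
    cds_partial: bool = False

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.transcript_id}: bad strand {self.strand!r}")
        for a, b in zip(self.exons, self.exons[1:]):
            if a[1] > b[0]:
                raise AnnotationError(
                    f"{self.transcript_id}: exons overlap or unsorted: {a}, {b}"
                )
        for seg in self.cds_segments:
            if not any(e[0] <= seg[0] and seg[1] <= e[1] for e in self.exons):
                raise AnnotationError(
                    f"{self.transcript_id}: CDS segment {seg} not inside any exon"
                )

    @property
    def span(self) -> Interval:
        return (self.exons[0][0], self.exons[-1][1])

    @property
    def cds_span(self) -> Interval | None:
        if not self.cds_segments:
            return None
        return (self.cds_segments[0][0], self.cds_segments[-1][1])

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds_segments)

    def cds_nt(self, genome: Mapping[str, GenomeSequence]) -> str:
        """Spliced CDS in genomic plus-strand orientation (5'->3' after
        strand handling by :func:`translate_cds`)."""
        chrom = genome[self.chrom]
        return "".join(chrom.fetch(s, e) for s, e in self.cds_segments)

    def cds_offset_to_genomic(self, offset: int) -> int:
        """Genomic position (0-based) of the CDS base at 0-based transcript
        CDS ``offset`` (offset 0 = first coding base in translation order)."""
        segs = self.cds_segments if self.strand == "+" else self.cds_segments[::-1]
        for s, e in segs:
            n = e - s
            if offset < n:
                return s + offset if self.strand == "+" else e - 1 - offset
            offset -= n
        raise ValueError(f"CDS offset beyond CDS of {self.transcript_id}")


@dataclass(frozen=True)
class IntronRecord:
    """One intron with the plus-strand numbering convention.

    ``plus_strand_index`` ascends with genomic coordinate (1-based) for all
    genes; ``display_index`` counts in transcript 5'->3' order, so for
    minus-strand genes it runs descending against the genome.
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    interval: Interval
    plus_strand_index: int
    display_index: int

    @property
    def length(self) -> int:
        return self.interval[1] - self.interval[0]


def enumerate_introns(t: TranscriptModel) -> list[IntronRecord]:
    """Introns between consecutive exons, numbered on the plus strand 5'->3'.

    A single-exon transcript yields an empty list.
    """
    n = len(t.exons) - 1
    out = []
    for i in range(n):
        interval = (t.exons[i][1], t.exons[i + 1][0])
        plus_idx = i + 1
        display = plus_idx if t.strand == "+" else n - plus_idx + 1
        out.append(
            IntronRecord(
                gene_id=t.gene_id,
                transcript_id=t.transcript_id,
                chrom=t.chrom,
                strand=t.strand,
                interval=interval,
                plus_strand_index=plus_idx,
                display_index=display,
            )
        )
    return out


def read_genome(fasta_path: str | Path) -> dict[str, GenomeSequence]:
    genome = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        genome[rec.id] = GenomeSequence(rec.id, str(rec.seq).upper())
    if not genome:
        raise ValueError(f"no sequences in {fasta_path}")
    return genome


def _compute_protein(
    transcript_id: str,
    strand: str,
    cds_segments: Sequence[Interval],
    chrom_seq: GenomeSequence,
) -> tuple[str, bool]:
    """Translate a CDS chain; returns (protein, partial_flag).

    Normalizes the stop-codon dialect: annotations may or may not include the
    terminal stop; the returned protein never ends at/with a stop.
    """
    nt = "".join(chrom_seq.fetch(s, e) for s, e in cds_segments)
    res = translate_cds_full(nt, strand)
    partial = res.partial_codon
    if partial:
        logger.warning("%s: CDS length not divisible by 3; flagged partial", transcript_id)
    return res.protein, partial


def read_annotation(
    gff3_path: str | Path,
    genome: Mapping[str, GenomeSequence],
) -> list[TranscriptModel]:
    """Build one TranscriptModel per mRNA from a GFF3 file.

    Exon/CDS records with unresolvable parents are rejected with a warning;
    a CDS segment outside all exons of its transcript is a hard error.
    """
    db = gffutils.create_db(
        str(gff3_path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    mrna_types = {"mRNA", "transcript"}
    mrnas = {}
    for ft in mrna_types:
        for f in db.features_of_type(ft):
            mrnas[f.id] = f

    exons_by_parent: dict[str, list[Interval]] = {}
    cds_by_parent: dict[str, list[Interval]] = {}
    for ftype, store in (("exon", exons_by_parent), ("CDS", cds_by_parent)):
        for f in db.features_of_type(ftype):
            parents = f.attributes.get("Parent", [])
            if not parents:
                logger.warning("%s record without Parent at %s:%d; rejected", ftype, f.seqid, f.start)
                continue
            for p in parents:
                if p not in mrnas:
                    logger.warning(
                        "%s record with unresolvable parent %r; rejected", ftype, p
                    )
                    continue
                store.setdefault(p, []).append((f.start - 1, f.end))

    models = []
    for tid, f in sorted(mrnas.items()):
        exons = sorted(exons_by_parent.get(tid, []))
        if not exons:
            logger.warning("mRNA %s has no exons; skipped", tid)
            continue
        cds = sorted(cds_by_parent.get(tid, []))
        for seg in cds:
            if not any(e[0] <= seg[0] and seg[1] <= e[1] for e in exons):
                raise AnnotationError(
                    f"transcript {tid}: CDS segment "
                    f"{seg[0] + 1}-{seg[1]} not contained in any exon"
                )
        gene_id = (f.attributes.get("Parent") or [tid.rsplit(".", 1)[0]])[0]
        if f.seqid not in genome:
            logger.warning("mRNA %s on unknown chromosome %s; skipped", tid, f.seqid)
            continue
        protein, partial = ("", False)
        if cds:
            protein, partial = _compute_protein(tid, f.strand, cds, genome[f.seqid])
        models.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=gene_id,
                chrom=f.seqid,
                strand=f.strand,
                exons=tuple(exons),
                cds_segments=tuple(cds),
                protein_sequence=protein,
                cds_partial=partial,
            )
        )
    return models


def transcripts_by_gene(
    transcripts: Iterable[TranscriptModel],
) -> dict[str, list[TranscriptModel]]:
    out: dict[str, list[TranscriptModel]] = {}
    for t in transcripts:
        out.setdefault(t.gene_id, []).append(t)
    for ts in out.values():
        ts.sort(key=lambda t: t.transcript_id)
    return out


def write_protein_fasta(
    transcripts: Iterable[TranscriptModel],
    path: str | Path,
    *,
    skip_partial: bool = True,
) -> int:
    """Write derived proteins with Araport11-style ``>GENE.N`` headers.

    Transcripts whose CDS length is not divisible by 3 are excluded by
    default (flagged-and-excluded policy for inconsistent annotations).
    """
    n = 0
    with open(path, "w") as fh:
        for t in transcripts:
            if not t.protein_sequence:
                continue
            if skip_partial and t.cds_partial:
                logger.warning("%s: partial CDS excluded from protein FASTA", t.transcript_id)
                continue
            fh.write(f">{t.transcript_id} | {t.gene_id}\n{t.protein_sequence}\n")
            n += 1
    return n
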