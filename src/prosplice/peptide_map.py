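"""Project peptides from protein coordinates onto the genome.

The arithmetic is the printed rule: residue *p* occupies CDS nucleotides
``3p-2 .. 3p`` (1-based).  The CDS nucleotide interval is pushed through the
cumulative CDS-segment lengths to genomic blocks; minus-strand transcripts
anchor CDS position 1 at the genomically-last CDS base.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from .genome_model import (
    GenomeSequence,
    Interval,
    TranscriptModel,
    translate_cds,
)


@dataclass(frozen=True)
class PeptideGenomicMap:
    peptide: str
    transcript_id: str
    protein_start: int  # 1-based residue positions, inclusive
    protein_end: int
    cds_nt_start: int  # 1-based CDS nucleotide positions, inclusive
    cds_nt_end: int
    chrom: str
    strand: str
    genomic_blocks: tuple[Interval, ...]  # ascending genomic order
    spans_junction: bool
    junctions_crossed: tuple[tuple[int, int], ...]  # (cds_seg_i, cds_seg_i+1), 1-based

    def __post_init__(self) -> None:
        if self.cds_nt_start != 3 * self.protein_start - 2:
            raise ValueError("cds_nt_start must be 3*protein_start - 2")
        if self.cds_nt_end != 3 * self.protein_end:
            raise ValueError("cds_nt_end must be 3*protein_end")
        if sum(e - s for s, e in self.genomic_blocks) != 3 * len(self.peptide):
            raise ValueError("block lengths must sum to 3 * peptide length")
        if self.spans_junction != (len(self.genomic_blocks) > 1):
            raise ValueError("spans_junction inconsistent with block count")

    @property
    def junction_gaps(self) -> tuple[Interval, ...]:
        """Genomic gaps (introns crossed) between consecutive blocks."""
        return tuple(
            (a[1], b[0]) for a, b in zip(self.genomic_blocks, self.genomic_blocks[1:])
        )


def locate_in_protein(peptide: str, protein_sequence: str) -> list[int]:
    """All exact occurrence start positions, 1-based; [] when absent."""
    out = []
    i = protein_sequence.find(peptide)
    while i != -1:
        out.append(i + 1)
        i = protein_sequence.find(peptide, i + 1)
    return out


def map_to_genome(
    peptide: str, t: TranscriptModel, protein_start: int
) -> PeptideGenomicMap:
    """Map one peptide occurrence on one transcript to genomic blocks."""
    protein_end = protein_start + len(peptide) - 1
    cds_nt_start = 3 * protein_start - 2
    cds_nt_end = 3 * protein_end
    if cds_nt_end > t.cds_length:
        raise ValueError(
            f"peptide {peptide} extends past CDS end of {t.transcript_id} "
            f"(needs {cds_nt_end} nt, CDS has {t.cds_length})"
        )
    # CDS segments in translation order
    segs = t.cds_segments if t.strand == "+" else t.cds_segments[::-1]
    blocks: list[Interval] = []
    crossed: list[tuple[int, int]] = []
    offset = 0  # cumulative CDS nt at segment start (0-based)
    lo, hi = cds_nt_start - 1, cds_nt_end  # 0-based half-open in CDS space
    for i, (s, e) in enumerate(segs):
        n = e - s
        seg_lo, seg_hi = offset, offset + n
        inter_lo, inter_hi = max(lo, seg_lo), min(hi, seg_hi)
        if inter_lo < inter_hi:
            if t.strand == "+":
                blocks.append((s + (inter_lo - seg_lo), s + (inter_hi - seg_lo)))
            else:
                blocks.append((e - (inter_hi - seg_lo), e - (inter_lo - seg_lo)))
            if inter_hi == seg_hi and hi > seg_hi:
                # peptide continues into the next translation-order segment
                crossed.append((i + 1, i + 2))
        offset += n
    blocks.sort()
    # merge abutting blocks (possible when CDS segments abut genomically)
    merged: list[Interval] = []
    for b in blocks:
        if merged and merged[-1][1] == b[0]:
            merged[-1] = (merged[-1][0], b[1])
        else:
            merged.append(b)
    blocks = [tuple(b) for b in merged]
    return PeptideGenomicMap(
        peptide=peptide,
        transcript_id=t.transcript_id,
        protein_start=protein_start,
        protein_end=protein_end,
        cds_nt_start=cds_nt_start,
        cds_nt_end=cds_nt_end,
        chrom=t.chrom,
        strand=t.strand,
        genomic_blocks=tuple(blocks),
        spans_junction=len(blocks) > 1,
        junctions_crossed=tuple(crossed),
    )


def map_peptides(
    peptides: Iterable[str],
    transcripts: Iterable[TranscriptModel],
    matched: Mapping[str, Iterable[str]] | None = None,
) -> list[PeptideGenomicMap]:
    """Map peptides onto (a subset of) transcripts, one record per occurrence.

    ``matched`` optionally restricts each peptide to its matched transcript
    ids.  Transcripts without annotated CDS are ignored.
    """
    by_id = {t.transcript_id: t for t in transcripts if t.cds_segments}
    out = []
    for pep in peptides:
        targets = (
            [by_id[tid] for tid in matched.get(pep, ()) if tid in by_id]
            if matched is not None
            else list(by_id.values())
        )
        for t in sorted(targets, key=lambda t: t.transcript_id):
            for pos in locate_in_protein(pep, t.protein_sequence):
                out.append(map_to_genome(pep, t, pos))
    return out


def extract_and_translate(
    m: PeptideGenomicMap, genome: Mapping[str, GenomeSequence]
) -> str:
    """Round-trip oracle helper: splice the blocks and translate strand-aware."""
    chrom = genome[m.chrom]
    nt = "".join(chrom.fetch(s, e) for s, e in m.genomic_blocks)
    return translate_cds(nt, m.strand)


def write_bed12(maps: Iterable[PeptideGenomicMap], path: str | Path) -> None:
    """BED12 export (blocks as blockSizes/blockStarts) for browser tracks."""
    with open(path, "w") as fh:
        for m in maps:
            start = m.genomic_blocks[0][0]
            end = m.genomic_blocks[-1][1]
            sizes = ",".join(str(e - s) for s, e in m.genomic_blocks)
            starts = ",".join(str(s - start) for s, e in m.genomic_blocks)
            fh.write(
                f"{m.chrom}\t{start}\t{end}\t{m.peptide}|{m.transcript_id}\t0\t"
                f"{m.strand}\t{start}\t{end}\t0\t{len(m.genomic_blocks)}\t"
                f"{sizes}\t{starts}\n"
            )


def maps_table(maps: Iterable[PeptideGenomicMap]):
    import pandas as pd

    rows = [
        {
            "peptide": m.peptide,
            "transcript_id": m.transcript_id,
            "protein_start": m.protein_start,
            "protein_end": m.protein_end,
            "cds_nt_start": m.cds_nt_start,
            "cds_nt_end": m.cds_nt_end,
            "chrom": m.chrom,
            "strand": m.strand,
            "blocks": ";".join(f"{s}-{e}" for s, e in m.genomic_blocks),
            "spans_junction": m.spans_junction,
        }
        for m in maps
    ]
    return pd.DataFrame(rows)
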