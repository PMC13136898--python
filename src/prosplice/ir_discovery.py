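"""Retained-intron discovery: depth ratios, candidate selection, and the
IR-inclusive custom protein database.

The intron depth ratio (IDratio) divides the mean read depth of an intron by
the mean depth of its flanking exons; terminal introns use only the internal
flanking exon (terminal-exon depths are unreliable).  Introns passing the
ratio threshold and absent from the annotated RI catalog are translated in
place to predict the protein outcome of their retention.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .as_events import ASEvent
from .genome_model import (
    GenomeSequence,
    Interval,
    IntronRecord,
    TranscriptModel,
    translate_cds_full,
)

logger = logging.getLogger(__name__)

OUTCOMES = ("truncated", "extended_in_frame", "frameshift_extended")


@dataclass(frozen=True)
class IntronDepthRecord:
    intron: IntronRecord
    sample_id: str
    intron_depth: float
    five_prime_exon_depth: float | None
    three_prime_exon_depth: float | None
    idratio: float | None  # None when the used exon depth is 0 or missing
    terminal_rule_applied: bool = False

    @property
    def is_defined(self) -> bool:
        return self.idratio is not None


def read_region_depths(path: str | Path) -> pd.DataFrame:
    """Region-depth TSV: chrom, start, end, sample, mean_depth (0-based half-open)."""
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "start", "end", "sample", "mean_depth"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def depths_from_bedgraph(path: str | Path, sample: str) -> pd.DataFrame:
    """Adapter: per-base bedGraph -> long-format per-base depth frame."""
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "depth"]
    )
    df["sample"] = sample
    return df


def mean_depth_over(
    bed: pd.DataFrame, chrom: str, interval: Interval, sample: str
) -> float:
    """Mean per-base depth of an interval from bedGraph-style rows."""
    s, e = interval
    rows = bed[(bed["chrom"] == chrom) & (bed["sample"] == sample)]
    total = 0.0
    for _, r in rows.iterrows():
        ov = max(0, min(e, r["end"]) - max(s, r["start"]))
        total += ov * r["depth"]
    return total / (e - s)


def _region_key(chrom: str, iv: Interval) -> tuple:
    return (chrom, iv[0], iv[1])


def compute_idratio(
    depths: pd.DataFrame,
    introns: Sequence[IntronRecord],
    transcripts: Mapping[str, TranscriptModel],
) -> list[IntronDepthRecord]:
    """One IntronDepthRecord per intron per sample.

    The depth table must contain rows for the introns and their flanking
    exons.  Terminal-intron rule: the first intron (transcript 5'-most) uses
    only its 3' (internal) flanking exon, the last intron only its 5'
    (internal) one.  With exactly one intron both flanks are terminal exons;
    their mean is used and the terminal flag is left unset.
    """
    lookup: dict[tuple, dict[str, float]] = {}
    for _, r in depths.iterrows():
        lookup.setdefault((r["chrom"], int(r["start"]), int(r["end"])), {})[
            str(r["sample"])
        ] = float(r["mean_depth"])
    samples = sorted({str(s) for s in depths["sample"]})

    out: list[IntronDepthRecord] = []
    for intron in introns:
        t = transcripts[intron.transcript_id]
        n_introns = len(t.exons) - 1
        i = intron.plus_strand_index - 1  # exon_i, exon_{i+1} flank it (plus order)
        left_exon, right_exon = t.exons[i], t.exons[i + 1]
        # plus-order terminal rule; strand decides which flank is 5' vs 3'
        use_left, use_right = True, True
        terminal = False
        if n_introns > 1:
            if i == 0:
                use_left, terminal = False, True
            if i == n_introns - 1:
                use_right, terminal = False, True
        intron_key = _region_key(intron.chrom, intron.interval)
        left_key = _region_key(intron.chrom, left_exon)
        right_key = _region_key(intron.chrom, right_exon)
        for sample in samples:
            idepth = lookup.get(intron_key, {}).get(sample)
            ldepth = lookup.get(left_key, {}).get(sample)
            rdepth = lookup.get(right_key, {}).get(sample)
            if intron.strand == "+":
                five, three = ldepth, rdepth
            else:
                five, three = rdepth, ldepth
            if idepth is None:
                logger.warning(
                    "intron %s:%d-%d missing depth for sample %s; flagged",
                    intron.chrom, *intron.interval, sample,
                )
                out.append(
                    IntronDepthRecord(intron, sample, math.nan, five, three, None, terminal)
                )
                continue
            flank_vals = []
            if use_left and ldepth is not None:
                flank_vals.append(ldepth)
            if use_right and rdepth is not None:
                flank_vals.append(rdepth)
            if not flank_vals or sum(flank_vals) == 0:
                ratio = None
            else:
                ratio = idepth / (sum(flank_vals) / len(flank_vals))
            out.append(
                IntronDepthRecord(
                    intron=intron,
                    sample_id=sample,
                    intron_depth=idepth,
                    five_prime_exon_depth=five,
                    three_prime_exon_depth=three,
                    idratio=ratio,
                    terminal_rule_applied=terminal,
                )
            )
    return out


def select_candidates(
    records: Sequence[IntronDepthRecord],
    annotated_ri: Sequence[ASEvent],
    threshold: float = 0.15,
    sample_groups: Mapping[str, Sequence[str]] | None = None,
    group_mode: str = "mean",
) -> list[IntronRecord]:
    """Introns whose IDratio passes ``threshold`` in ANY sample group.

    ``sample_groups`` maps group name (e.g. WT / mutant) to sample ids; when
    omitted every sample is its own group.  ``group_mode`` is "mean" (group
    mean IDratio, default) or "any" (any single replicate).  Introns whose
    interval equals an annotated RI event's discriminating region are
    excluded as redundant.
    """
    if group_mode not in ("mean", "any"):
        raise ValueError("group_mode must be 'mean' or 'any'")
    annotated_intervals = {
        (ev.chrom, region)
        for ev in annotated_ri
        if ev.event_type == "RI"
        for region in ev.discriminating_region
    }
    by_intron: dict[tuple, dict[str, list[float]]] = {}
    intron_obj: dict[tuple, IntronRecord] = {}
    for r in records:
        if not r.is_defined:
            continue
        key = (_region_key(r.intron.chrom, r.intron.interval), r.intron.transcript_id)
        by_intron.setdefault(key, {}).setdefault(r.sample_id, []).append(r.idratio)
        intron_obj[key] = r.intron

    selected: list[IntronRecord] = []
    seen: set[tuple] = set()
    for key, per_sample in sorted(by_intron.items()):
        intron = intron_obj[key]
        if (intron.chrom, intron.interval) in annotated_intervals:
            continue
        groups = (
            {g: list(ss) for g, ss in sample_groups.items()}
            if sample_groups
            else {s: [s] for s in per_sample}
        )
        passed = False
        for g, sample_ids in groups.items():
            vals = [v for s in sample_ids for v in per_sample.get(s, [])]
            if not vals:
                continue
            if group_mode == "mean":
                passed = sum(vals) / len(vals) >= threshold
            else:
                passed = any(v >= threshold for v in vals)
            if passed:
                break
        dedup_key = (intron.chrom, intron.interval)
        if passed and dedup_key not in seen:
            seen.add(dedup_key)
            selected.append(intron)
    return selected


def fit_intron_to_transcripts(
    intron_interval: Interval,
    transcripts: Sequence[TranscriptModel],
) -> list[tuple[TranscriptModel, str]]:
    """Transcripts the intron fits without gaps.

    Returns (transcript, mode) with mode "internal" (exactly between two
    consecutive exons), "upstream" (abutting the genomically-first exon) or
    "downstream" (abutting the genomically-last exon).
    """
    s, e = intron_interval
    out = []
    for t in transcripts:
        mode = None
        for i in range(len(t.exons) - 1):
            if t.exons[i][1] == s and t.exons[i + 1][0] == e:
                mode = "internal"
                break
        if mode is None:
            if e == t.exons[0][0]:
                mode = "upstream"
            elif s == t.exons[-1][1]:
                mode = "downstream"
        if mode:
            out.append((t, mode))
    return out


@dataclass(frozen=True)
class CustomProteinEntry:
    accession: str  # GENE.N_IRk
    base_transcript_id: str
    retained_intron: Interval
    protein_sequence: str
    outcome: str
    delta_length_aa: int
    in_cds: bool = True

    def __post_init__(self) -> None:
        if self.outcome not in OUTCOMES:
            raise ValueError(f"unknown outcome {self.outcome!r}")
        if "*" in self.protein_sequence:
            raise ValueError("protein sequence must not contain stop symbols")
        if (self.outcome == "truncated") != (self.delta_length_aa < 0):
            raise ValueError("outcome=truncated iff protein shorter than base")


def build_ir_protein(
    t: TranscriptModel,
    intron_interval: Interval,
    genome: Mapping[str, GenomeSequence],
    intron_index: int | None = None,
) -> CustomProteinEntry:
    """Insert the intron into the CDS chain and translate the result.

    Translation starts at the annotated CDS start of the base transcript and
    stops at the first in-frame stop codon.  Introns fitting at UTR-only
    junctions yield an entry flagged ``in_cds=False`` with the base protein.
    """
    s, e = intron_interval
    if intron_index is None:
        intron_index = next(
            (
                i + 1
                for i in range(len(t.exons) - 1)
                if t.exons[i][1] == s and t.exons[i + 1][0] == e
            ),
            0,
        )
    accession = f"{t.transcript_id}_IR{intron_index}"
    cds = list(t.cds_segments)
    cds_span = t.cds_span
    in_cds = (
        cds_span is not None
        and cds_span[0] < s
        and e < cds_span[1]
        and any(cds[i][1] == s and cds[i + 1][0] == e for i in range(len(cds) - 1))
    )
    chrom = genome[t.chrom]
    base_len = len(t.protein_sequence)
    if not in_cds:
        return CustomProteinEntry(
            accession=accession,
            base_transcript_id=t.transcript_id,
            retained_intron=intron_interval,
            protein_sequence=t.protein_sequence,
            outcome=_zero_outcome(),
            delta_length_aa=0,
            in_cds=False,
        )
    segments = sorted(cds + [intron_interval])
    nt = "".join(chrom.fetch(a, b) for a, b in segments)
    res = translate_cds_full(nt, t.strand)
    protein = res.protein
    delta = len(protein) - base_len
    intron_len = e - s
    if delta < 0:
        outcome = "truncated"
    elif intron_len % 3 == 0 and delta == intron_len // 3:
        # frame preserved and no stop introduced: the intron contributes
        # exactly length/3 residues
        outcome = "extended_in_frame"
    else:
        outcome = "frameshift_extended"
    return CustomProteinEntry(
        accession=accession,
        base_transcript_id=t.transcript_id,
        retained_intron=intron_interval,
        protein_sequence=protein,
        outcome=outcome,
        delta_length_aa=delta,
        in_cds=True,
    )


def _zero_outcome() -> str:
    # non-CDS retention leaves the protein unchanged; report as in-frame no-op
    return "extended_in_frame"


def build_candidate_entries(
    candidates: Sequence[IntronRecord],
    transcripts: Sequence[TranscriptModel],
    genome: Mapping[str, GenomeSequence],
) -> list[CustomProteinEntry]:
    """Fit each candidate intron to its gene's transcripts and build entries."""
    from .genome_model import transcripts_by_gene

    by_gene = transcripts_by_gene(transcripts)
    entries: dict[str, CustomProteinEntry] = {}
    for intron in candidates:
        gene_ts = by_gene.get(intron.gene_id, [])
        for t, mode in fit_intron_to_transcripts(intron.interval, gene_ts):
            entry = build_ir_protein(
                t, intron.interval, genome, intron_index=intron.plus_strand_index
            )
            entries.setdefault(entry.accession, entry)
    return [entries[k] for k in sorted(entries)]


def summarize_outcomes(
    entry_sets: Mapping[str, Sequence[CustomProteinEntry]],
) -> pd.DataFrame:
    """Counts and truncated fractions per named entry set (e.g. annotated /
    unannotated)."""
    rows = []
    for name, entries in entry_sets.items():
        cds_entries = [e for e in entries if e.in_cds]
        n = len(cds_entries)
        if n == 0:
            continue
        n_trunc = sum(1 for e in cds_entries if e.outcome == "truncated")
        rows.append(
            {
                "set": name,
                "n_events": n,
                "n_truncated": n_trunc,
                "truncated_fraction": n_trunc / n,
            }
        )
    return pd.DataFrame(rows, columns=["set", "n_events", "n_truncated", "truncated_fraction"])


def write_custom_database(
    base_fasta: str | Path,
    entries: Sequence[CustomProteinEntry],
    out_path: str | Path,
) -> int:
    """Append IR entries to the base protein FASTA.

    Entries whose sequence duplicates a base entry are dropped and logged
    (a frame-preserved IR may equal an annotated isoform); an accession
    collision with the base database is a hard error.  Returns the number of
    records written.
    """
    from Bio import SeqIO

    base_records = list(SeqIO.parse(str(base_fasta), "fasta"))
    base_ids = {r.id for r in base_records}
    base_seqs = {str(r.seq) for r in base_records}
    n = len(base_records)
    with open(base_fasta, "rb") as src, open(out_path, "wb") as dst:
        data = src.read()
        dst.write(data)
        needs_newline = bool(data) and not data.endswith(b"\n")
    with open(out_path, "a") as fh:
        if needs_newline:
            fh.write("\n")
        for e in entries:
            if e.accession in base_ids:
                raise ValueError(f"accession collision with base database: {e.accession}")
            if e.protein_sequence in base_seqs:
                logger.warning(
                    "IR entry %s identical to an annotated isoform; dropped", e.accession
                )
                continue
            desc = (
                f"{e.accession} base={e.base_transcript_id} "
                f"intron={e.retained_intron[0]}-{e.retained_intron[1]} "
                f"outcome={e.outcome} delta_aa={e.delta_length_aa:+d}"
            )
            fh.write(f">{desc}\n{e.protein_sequence}\n")
            n += 1
    return n


def idratio_table(records: Iterable[IntronDepthRecord]) -> pd.DataFrame:
    rows = [
        {
            "gene_id": r.intron.gene_id,
            "transcript_id": r.intron.transcript_id,
            "chrom": r.intron.chrom,
            "start": r.intron.interval[0],
            "end": r.intron.interval[1],
            "strand": r.intron.strand,
            "plus_strand_index": r.intron.plus_strand_index,
            "display_index": r.intron.display_index,
            "sample": r.sample_id,
            "intron_depth": r.intron_depth,
            "idratio": r.idratio if r.idratio is not None else float("nan"),
            "terminal_rule": r.terminal_rule_applied,
        }
        for r in records
    ]
    return pd.DataFrame(rows)
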