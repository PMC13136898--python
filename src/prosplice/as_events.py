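"""SUPPA-style alternative-splicing event catalog from transcript models.

Event ids follow the SUPPA v2.3 ioe dialect (``GENE;TYPE:chr:coords:strand``
with 1-based coordinates); see the README for the per-type coordinate order.
The retained-intron generator follows the "variable" interpretation: flanking
exon boundaries may differ across transcript pairs and events are
deduplicated by intron interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .genome_model import Interval, TranscriptModel, transcripts_by_gene

EVENT_TYPES = ("RI", "SE", "A5", "A3", "AF", "AL", "MX")


@dataclass(frozen=True)
class ASEvent:
    event_id: str
    gene_id: str
    event_type: str
    chrom: str
    strand: str
    anchor_coords: tuple[int, ...]
    # interval(s) exonic only in the inclusion form (0-based half-open)
    discriminating_region: tuple[Interval, ...]
    # for AF/AL/MX: interval(s) exonic only in the exclusion form
    exclusion_region: tuple[Interval, ...] = ()
    inclusion_transcripts: frozenset[str] = frozenset()
    exclusion_transcripts: frozenset[str] = frozenset()
    region_label: str | None = None  # set by restrict_to_cds: "CDS" or "UTR"

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.event_type!r}")
        if self.inclusion_transcripts & self.exclusion_transcripts:
            raise ValueError(f"{self.event_id}: inclusion/exclusion sets overlap")


def _c1(pos0: int) -> int:
    """0-based position -> 1-based (starts)."""
    return pos0 + 1


def _introns(t: TranscriptModel) -> list[Interval]:
    return [(t.exons[i][1], t.exons[i + 1][0]) for i in range(len(t.exons) - 1)]


def _has_intron(t: TranscriptModel, iv: Interval) -> bool:
    return iv in _introns(t)


def _exon_covering(t: TranscriptModel, iv: Interval) -> Interval | None:
    """Exon strictly covering interval iv with >=1 nt on each side."""
    for s, e in t.exons:
        if s < iv[0] and e > iv[1]:
            return (s, e)
    return None


def _ri_events(gene_id: str, ts: Sequence[TranscriptModel]) -> list[ASEvent]:
    chrom, strand = ts[0].chrom, ts[0].strand
    # candidate introns = introns of any transcript retained by another
    by_intron: dict[Interval, tuple[set[str], set[str], list[tuple[Interval, Interval]]]] = {}
    for t_spl in ts:
        introns = _introns(t_spl)
        for i, iv in enumerate(introns):
            if not any(_exon_covering(o, iv) for o in ts if o is not t_spl):
                continue
            incl = {o.transcript_id for o in ts if _exon_covering(o, iv)}
            excl = {o.transcript_id for o in ts if _has_intron(o, iv)}
            flanks = (t_spl.exons[i], t_spl.exons[i + 1])
            entry = by_intron.setdefault(iv, (set(), set(), []))
            entry[0].update(incl)
            entry[1].update(excl)
            entry[2].append(flanks)
    events = []
    for iv, (incl, excl, flank_list) in sorted(by_intron.items()):
        (f1s, f1e), (f2s, f2e) = min(flank_list)  # deterministic representative
        # RI:chr:s1:e1-s2:e2 (1-based): exon1 start, exon1 end, exon2 start, exon2 end
        anchor = (_c1(f1s), f1e, _c1(f2s), f2e)
        eid = f"{gene_id};RI:{chrom}:{anchor[0]}:{anchor[1]}-{anchor[2]}:{anchor[3]}:{strand}"
        events.append(
            ASEvent(
                event_id=eid,
                gene_id=gene_id,
                event_type="RI",
                chrom=chrom,
                strand=strand,
                anchor_coords=anchor,
                discriminating_region=(iv,),
                inclusion_transcripts=frozenset(incl - excl),
                exclusion_transcripts=frozenset(excl),
            )
        )
    return events


def _se_events(gene_id: str, ts: Sequence[TranscriptModel]) -> list[ASEvent]:
    chrom, strand = ts[0].chrom, ts[0].strand
    # inclusion pattern: consecutive exon triple (..,aE),(B),(cS,..)
    found: dict[tuple, tuple[set[str], set[str]]] = {}
    for t_in in ts:
        ex = t_in.exons
        for i in range(1, len(ex) - 1):
            a_e = ex[i - 1][1]
            b = ex[i]
            c_s = ex[i + 1][0]
            skip_iv = (a_e, c_s)
            excl = {o.transcript_id for o in ts if _has_intron(o, skip_iv)}
            if not excl:
                continue
            incl = {
                o.transcript_id
                for o in ts
                if any(
                    o.exons[j - 1][1] == a_e
                    and o.exons[j] == b
                    and o.exons[j + 1][0] == c_s
                    for j in range(1, len(o.exons) - 1)
                )
            }
            key = (a_e, b, c_s)
            entry = found.setdefault(key, (set(), set()))
            entry[0].update(incl)
            entry[1].update(excl)
    events = []
    for (a_e, b, c_s), (incl, excl) in sorted(found.items()):
        # SE:chr:e1-s2:e2-s3
        anchor = (a_e, _c1(b[0]), b[1], _c1(c_s))
        eid = f"{gene_id};SE:{chrom}:{anchor[0]}-{anchor[1]}:{anchor[2]}-{anchor[3]}:{strand}"
        events.append(
            ASEvent(
                event_id=eid,
                gene_id=gene_id,
                event_type="SE",
                chrom=chrom,
                strand=strand,
                anchor_coords=anchor,
                discriminating_region=(b,),
                inclusion_transcripts=frozenset(incl - excl),
                exclusion_transcripts=frozenset(excl - incl),
            )
        )
    return events


def _alt_site_events(gene_id: str, ts: Sequence[TranscriptModel]) -> list[ASEvent]:
    """A5/A3: intron pairs sharing one boundary and differing at the other."""
    chrom, strand = ts[0].chrom, ts[0].strand
    found: dict[tuple, tuple[str, Interval, set[str], set[str]]] = {}
    for t1, t2 in combinations(ts, 2):
        for iv1 in _introns(t1):
            for iv2 in _introns(t2):
                if iv1 == iv2:
                    continue
                if iv1[1] == iv2[1] and iv1[0] != iv2[0]:
                    # differ at genomic-left boundary (donor on +, acceptor on -)
                    d_short, d_long = sorted((iv1[0], iv2[0]))
                    disc = (d_short, d_long)
                    etype = "A5" if strand == "+" else "A3"
                    long_iv = (d_long, iv1[1])  # shorter exon... longer exon form
                    short_iv = (d_short, iv1[1])
                elif iv1[0] == iv2[0] and iv1[1] != iv2[1]:
                    a_short, a_long = sorted((iv1[1], iv2[1]))
                    disc = (a_short, a_long)
                    etype = "A3" if strand == "+" else "A5"
                    long_iv = (iv1[0], a_short)  # short intron -> long exon form
                    short_iv = (iv1[0], a_long)
                else:
                    continue
                # inclusion form carries disc as exon sequence: its intron is
                # the one NOT containing disc
                if disc[0] >= long_iv[0] and disc[1] <= long_iv[1]:
                    long_iv, short_iv = short_iv, long_iv
                incl = {o.transcript_id for o in ts if _has_intron(o, long_iv)}
                excl = {o.transcript_id for o in ts if _has_intron(o, short_iv)}
                # require the inclusion transcript's exon to actually cover disc
                incl = {
                    tid
                    for tid in incl
                    if any(
                        s <= disc[0] and disc[1] <= e
                        for o in ts
                        if o.transcript_id == tid
                        for s, e in o.exons
                    )
                }
                if not incl or not excl:
                    continue
                key = (etype, long_iv, short_iv)
                if key in found:
                    found[key][2].update(incl)
                    found[key][3].update(excl)
                else:
                    found[key] = (etype, disc, set(incl), set(excl))
    events = []
    for (etype, long_iv, short_iv), (_, disc, incl, excl) in sorted(found.items()):
        # A5/A3:chr:<inclusion junction e-s>:<exclusion junction e-s>
        anchor = (long_iv[0], _c1(long_iv[1]), short_iv[0], _c1(short_iv[1]))
        eid = (
            f"{gene_id};{etype}:{chrom}:{anchor[0]}-{anchor[1]}:"
            f"{anchor[2]}-{anchor[3]}:{strand}"
        )
        events.append(
            ASEvent(
                event_id=eid,
                gene_id=gene_id,
                event_type=etype,
                chrom=chrom,
                strand=strand,
                anchor_coords=anchor,
                discriminating_region=(disc,),
                inclusion_transcripts=frozenset(incl - excl),
                exclusion_transcripts=frozenset(excl - incl),
            )
        )
    return events


def _overlaps(a: Interval, b: Interval) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def _terminal_events(
    gene_id: str, ts: Sequence[TranscriptModel], which: str
) -> list[ASEvent]:
    """AF/AL: distinct non-overlapping terminal exons joining a shared junction."""
    chrom, strand = ts[0].chrom, ts[0].strand
    events: dict[tuple, ASEvent] = {}
    # transcript-first exon: on '+' it is the genomic-left end for AF and the
    # genomic-right end for AL; flipped on '-'
    left_terminal = (which == "AF") == (strand == "+")
    for t1, t2 in combinations(ts, 2):
        if len(t1.exons) < 2 or len(t2.exons) < 2:
            continue
        if left_terminal:
            f1, f2 = t1.exons[0], t2.exons[0]
            shared1, shared2 = t1.exons[1][0], t2.exons[1][0]
        else:
            f1, f2 = t1.exons[-1], t2.exons[-1]
            shared1, shared2 = t1.exons[-2][1], t2.exons[-2][1]
        if shared1 != shared2 or f1 == f2 or _overlaps(f1, f2):
            continue
        # inclusion = transcript-5'-most (AF) / 3'-most (AL) distal exon
        if left_terminal:
            incl_exon, excl_exon = (f1, f2) if f1[0] < f2[0] else (f2, f1)
        else:
            incl_exon, excl_exon = (f1, f2) if f1[1] > f2[1] else (f2, f1)
        shared = shared1
        anchor = (
            _c1(incl_exon[0]),
            incl_exon[1],
            _c1(excl_exon[0]),
            excl_exon[1],
            _c1(shared) if left_terminal else shared,
        )
        key = anchor
        incl_set = {
            o.transcript_id
            for o in ts
            if len(o.exons) >= 2
            and (o.exons[0] if left_terminal else o.exons[-1]) == incl_exon
            and (o.exons[1][0] if left_terminal else o.exons[-2][1]) == shared
        }
        excl_set = {
            o.transcript_id
            for o in ts
            if len(o.exons) >= 2
            and (o.exons[0] if left_terminal else o.exons[-1]) == excl_exon
            and (o.exons[1][0] if left_terminal else o.exons[-2][1]) == shared
        }
        eid = (
            f"{gene_id};{which}:{chrom}:"
            + ":".join(str(x) for x in anchor)
            + f":{strand}"
        )
        ev = ASEvent(
            event_id=eid,
            gene_id=gene_id,
            event_type=which,
            chrom=chrom,
            strand=strand,
            anchor_coords=anchor,
            discriminating_region=(incl_exon,),
            exclusion_region=(excl_exon,),
            inclusion_transcripts=frozenset(incl_set),
            exclusion_transcripts=frozenset(excl_set),
        )
        events[key] = ev
    return [events[k] for k in sorted(events)]


def _mx_events(gene_id: str, ts: Sequence[TranscriptModel]) -> list[ASEvent]:
    chrom, strand = ts[0].chrom, ts[0].strand
    found: dict[tuple, ASEvent] = {}
    for t1, t2 in combinations(ts, 2):
        for i in range(1, len(t1.exons) - 1):
            for j in range(1, len(t2.exons) - 1):
                a_e1, b, d_s1 = t1.exons[i - 1][1], t1.exons[i], t1.exons[i + 1][0]
                a_e2, c, d_s2 = t2.exons[j - 1][1], t2.exons[j], t2.exons[j + 1][0]
                if a_e1 != a_e2 or d_s1 != d_s2 or b == c or _overlaps(b, c):
                    continue
                first, second = (b, c) if b[0] < c[0] else (c, b)
                # each alternative exon must be absent from the other form
                anchor = (a_e1, _c1(first[0]), first[1], _c1(second[0]), second[1], _c1(d_s1))
                incl_set = {
                    o.transcript_id
                    for o in ts
                    if any(
                        o.exons[k - 1][1] == a_e1
                        and o.exons[k] == first
                        and o.exons[k + 1][0] == d_s1
                        for k in range(1, len(o.exons) - 1)
                    )
                }
                excl_set = {
                    o.transcript_id
                    for o in ts
                    if any(
                        o.exons[k - 1][1] == a_e1
                        and o.exons[k] == second
                        and o.exons[k + 1][0] == d_s1
                        for k in range(1, len(o.exons) - 1)
                    )
                }
                if not incl_set or not excl_set or (incl_set & excl_set):
                    continue
                eid = (
                    f"{gene_id};MX:{chrom}:{anchor[0]}-{anchor[1]}:{anchor[2]}-"
                    f"{anchor[5]}:{anchor[0]}-{anchor[3]}:{anchor[4]}-{anchor[5]}:{strand}"
                )
                found[anchor] = ASEvent(
                    event_id=eid,
                    gene_id=gene_id,
                    event_type="MX",
                    chrom=chrom,
                    strand=strand,
                    anchor_coords=anchor,
                    discriminating_region=(first,),
                    exclusion_region=(second,),
                    inclusion_transcripts=frozenset(incl_set),
                    exclusion_transcripts=frozenset(excl_set),
                )
    return [found[k] for k in sorted(found)]


_GENERATORS = {
    "RI": _ri_events,
    "SE": _se_events,
    "A5": _alt_site_events,
    "A3": _alt_site_events,
    "AF": lambda g, ts: _terminal_events(g, ts, "AF"),
    "AL": lambda g, ts: _terminal_events(g, ts, "AL"),
    "MX": _mx_events,
}


def generate_events(
    transcripts: Iterable[TranscriptModel],
    types: Sequence[str] = EVENT_TYPES,
) -> list[ASEvent]:
    """Enumerate AS events across all genes with >=2 transcripts.

    Events are deduplicated by (type, anchor coordinates); an empty catalog
    is valid.
    """
    bad = set(types) - set(EVENT_TYPES)
    if bad:
        raise ValueError(f"unknown event types: {sorted(bad)}")
    events: list[ASEvent] = []
    for gene_id, ts in sorted(transcripts_by_gene(transcripts).items()):
        if len(ts) < 2:
            continue
        gene_events: list[ASEvent] = []
        done: set[str] = set()
        for etype in types:
            if etype in ("A5", "A3"):
                if "A5A3" in done:
                    continue
                done.add("A5A3")
                gene_events.extend(
                    e for e in _alt_site_events(gene_id, ts) if e.event_type in types
                )
            else:
                gene_events.extend(_GENERATORS[etype](gene_id, ts))
        events.extend(e for e in gene_events if e.inclusion_transcripts and e.exclusion_transcripts)
    return events


def restrict_to_cds(
    events: Iterable[ASEvent],
    transcripts: Iterable[TranscriptModel],
) -> list[ASEvent]:
    """Label events CDS/UTR; return only those overlapping coding sequence.

    An event is CDS if any discriminating (or exclusion-form) interval
    overlaps a CDS segment of >=1 participating transcript by >=1 nt.
    """
    by_id = {t.transcript_id: t for t in transcripts}
    out = []
    for ev in events:
        participants = ev.inclusion_transcripts | ev.exclusion_transcripts
        regions = ev.discriminating_region + ev.exclusion_region
        is_cds = any(
            _overlaps(region, seg)
            for tid in participants
            if tid in by_id
            for seg in by_id[tid].cds_segments
            for region in regions
        )
        labeled = replace(ev, region_label="CDS" if is_cds else "UTR")
        if is_cds:
            out.append(labeled)
    return out


def label_regions(
    events: Iterable[ASEvent], transcripts: Iterable[TranscriptModel]
) -> list[ASEvent]:
    """Like :func:`restrict_to_cds` but keeps UTR events (labeled)."""
    by_id = {t.transcript_id: t for t in transcripts}
    out = []
    for ev in events:
        participants = ev.inclusion_transcripts | ev.exclusion_transcripts
        regions = ev.discriminating_region + ev.exclusion_region
        is_cds = any(
            _overlaps(region, seg)
            for tid in participants
            if tid in by_id
            for seg in by_id[tid].cds_segments
            for region in regions
        )
        out.append(replace(ev, region_label="CDS" if is_cds else "UTR"))
    return out


def write_ioe(events: Iterable[ASEvent], path: str | Path) -> None:
    """ioe-like TSV: seqname, gene_id, event_id, inclusion, total transcripts."""
    with open(path, "w") as fh:
        fh.write("seqname\tgene_id\tevent_id\talternative_transcripts\ttotal_transcripts\n")
        for ev in events:
            total = sorted(ev.inclusion_transcripts | ev.exclusion_transcripts)
            fh.write(
                f"{ev.chrom}\t{ev.gene_id}\t{ev.event_id}\t"
                f"{','.join(sorted(ev.inclusion_transcripts))}\t{','.join(total)}\n"
            )


def write_bed(events: Iterable[ASEvent], path: str | Path) -> None:
    """BED of discriminating regions (one line per interval)."""
    with open(path, "w") as fh:
        for ev in events:
            for s, e in ev.discriminating_region:
                fh.write(f"{ev.chrom}\t{s}\t{e}\t{ev.event_id}\t0\t{ev.strand}\n")
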