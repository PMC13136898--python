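"""Call proteomically supported splicing events from peptide genomic maps.

Coordinate-overlap evidence (>=1 nt by default) supports the inclusion form
of RI/A5/A3/AF/AL events; junction evidence supports exclusion forms and is
required for SE and MX calls.  AF/AL events additionally accept peptides
fully inside the alternative terminal exon's region for either form.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .as_events import ASEvent
from .genome_model import Interval
from .peptide_map import PeptideGenomicMap


@dataclass(frozen=True)
class EventSupport:
    event_id: str
    event_type: str
    supported_form: str  # "inclusion" | "exclusion"
    evidence_kind: str  # "overlap" | "junction"
    peptides: tuple[str, ...]

    @property
    def n_peptides(self) -> int:
        return len(self.peptides)


@dataclass(frozen=True)
class ConflictRecord:
    """Peptide overlapping a discriminating region while mapped only to
    exclusion-form transcripts; reported, never counted."""

    event_id: str
    peptide: str
    transcript_id: str


def _overlap_nt(a: Interval, b: Interval) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def _blocks_overlap(m: PeptideGenomicMap, regions: Sequence[Interval], min_nt: int) -> bool:
    return any(
        _overlap_nt(block, region) >= min_nt
        for block in m.genomic_blocks
        for region in regions
    )


def _within(m: PeptideGenomicMap, region: Interval) -> bool:
    return (
        len(m.genomic_blocks) >= 1
        and m.genomic_blocks[0][0] >= region[0]
        and m.genomic_blocks[-1][1] <= region[1]
    )


def _has_junction(m: PeptideGenomicMap, gap: Interval) -> bool:
    return gap in m.junction_gaps


def _junction_into(m: PeptideGenomicMap, exon: Interval) -> bool:
    """Peptide splices into or out of the given exon."""
    return any(gap[1] == exon[0] or gap[0] == exon[1] for gap in m.junction_gaps)


def call_events(
    maps: Sequence[PeptideGenomicMap],
    events: Sequence[ASEvent],
    min_overlap_nt: int = 1,
) -> tuple[list[EventSupport], list[ConflictRecord]]:
    """Integrate peptide maps with the event catalog.

    Returns (supports, conflicts); each (event, form) is reported once with
    pooled peptides.
    """
    supports: list[EventSupport] = []
    conflicts: list[ConflictRecord] = []
    by_chrom: dict[str, list[PeptideGenomicMap]] = {}
    for m in maps:
        by_chrom.setdefault(m.chrom, []).append(m)

    for ev in events:
        incl_peps: dict[str, str] = {}  # peptide -> evidence kind
        excl_peps: dict[str, str] = {}
        disc = ev.discriminating_region
        for m in by_chrom.get(ev.chrom, []):
            on_incl = m.transcript_id in ev.inclusion_transcripts
            on_excl = m.transcript_id in ev.exclusion_transcripts
            if not (on_incl or on_excl):
                continue
            if ev.event_type in ("RI", "A5", "A3"):
                if _blocks_overlap(m, disc, min_overlap_nt):
                    if on_incl:
                        incl_peps.setdefault(m.peptide, "overlap")
                    else:
                        conflicts.append(ConflictRecord(ev.event_id, m.peptide, m.transcript_id))
                if on_excl and any(
                    gap[0] <= disc[0][0] and gap[1] >= disc[0][1] for gap in m.junction_gaps
                ) and any(
                    gap[0] == disc[0][0] or gap[1] == disc[0][1] for gap in m.junction_gaps
                ):
                    excl_peps.setdefault(m.peptide, "junction")
            elif ev.event_type in ("AF", "AL"):
                if on_incl and (
                    _blocks_overlap(m, disc, min_overlap_nt)
                    or _junction_into(m, disc[0])
                ):
                    kind = "overlap" if _blocks_overlap(m, disc, min_overlap_nt) else "junction"
                    incl_peps.setdefault(m.peptide, kind)
                if on_excl and ev.exclusion_region:
                    if _blocks_overlap(m, ev.exclusion_region, min_overlap_nt) or _junction_into(
                        m, ev.exclusion_region[0]
                    ):
                        kind = (
                            "overlap"
                            if _blocks_overlap(m, ev.exclusion_region, min_overlap_nt)
                            else "junction"
                        )
                        excl_peps.setdefault(m.peptide, kind)
                elif _blocks_overlap(m, disc, min_overlap_nt) and not on_incl:
                    conflicts.append(ConflictRecord(ev.event_id, m.peptide, m.transcript_id))
            elif ev.event_type == "SE":
                exon = disc[0]
                a_e, skip_end = ev.anchor_coords[0], ev.anchor_coords[3] - 1
                if on_incl and _junction_into(m, exon):
                    incl_peps.setdefault(m.peptide, "junction")
                if on_excl and _has_junction(m, (a_e, skip_end)):
                    excl_peps.setdefault(m.peptide, "junction")
            elif ev.event_type == "MX":
                if on_incl and _junction_into(m, disc[0]):
                    incl_peps.setdefault(m.peptide, "junction")
                if on_excl and ev.exclusion_region and _junction_into(m, ev.exclusion_region[0]):
                    excl_peps.setdefault(m.peptide, "junction")

        for form, peps in (("inclusion", incl_peps), ("exclusion", excl_peps)):
            if peps:
                kinds = set(peps.values())
                kind = "junction" if kinds == {"junction"} else "overlap"
                supports.append(
                    EventSupport(
                        event_id=ev.event_id,
                        event_type=ev.event_type,
                        supported_form=form,
                        evidence_kind=kind,
                        peptides=tuple(sorted(peps)),
                    )
                )
    return supports, conflicts


def summarize_event_counts(supports: Iterable[EventSupport]) -> pd.DataFrame:
    """Distinct supported events per type, plus a both-forms tally."""
    events_per_type: dict[str, set[str]] = {t: set() for t in ("RI", "SE", "A5", "A3", "AF", "AL", "MX")}
    forms: dict[str, set[str]] = {}
    types: dict[str, str] = {}
    for s in supports:
        events_per_type.setdefault(s.event_type, set()).add(s.event_id)
        forms.setdefault(s.event_id, set()).add(s.supported_form)
        types[s.event_id] = s.event_type
    both = Counter(types[eid] for eid, f in forms.items() if f == {"inclusion", "exclusion"})
    rows = [
        {
            "event_type": t,
            "n_events": len(eids),
            "n_both_forms": both.get(t, 0),
        }
        for t, eids in sorted(events_per_type.items())
    ]
    return pd.DataFrame(rows)


def supports_table(supports: Iterable[EventSupport]) -> pd.DataFrame:
    rows = [
        {
            "event_id": s.event_id,
            "event_type": s.event_type,
            "form": s.supported_form,
            "evidence": s.evidence_kind,
            "n_peptides": s.n_peptides,
            "peptides": ",".join(s.peptides),
        }
        for s in supports
    ]
    return pd.DataFrame(
        rows,
        columns=["event_id", "event_type", "form", "evidence", "n_peptides", "peptides"],
    )


def write_supports(supports: Iterable[EventSupport], path: str | Path) -> None:
    supports_table(supports).to_csv(path, sep="\t", index=False)
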