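"""Peptide-level filtering and the isoform-specificity disjointness rule.

Pipeline: ingest engine TSVs, drop decoys, merge on plain sequence, re-anchor
peptides in proteins (with the N-terminal Met-loss adjustment), then classify
each peptide at its gene locus.  A peptide is *isoform-specific* iff its
matched-isoform set is disjoint from the matched-isoform set of at least one
other peptide at the same locus.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass, field, replace
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

CATEGORIES = (
    "single_isoform_gene",
    "multi_gene",
    "shared_all_isoforms",
    "isoform_specific",
    "subset_unpaired",
)

_MOD_BRACKETS = re.compile(r"\[[^\]]*\]|\([^)]*\)|\{[^}]*\}")


def strip_modifications(sequence: str) -> str:
    """Reduce an engine-annotated peptide string to its plain sequence.

    Handles bracketed mass/name annotations (``M[15.9949]``, ``M(ox)``),
    lowercase modified residues, and terminal markers like ``K.PEPTIDER.A``.
    """
    s = _MOD_BRACKETS.sub("", sequence)
    if s.count(".") == 2:  # X.PEPTIDE.Y flanking-residue notation
        s = s.split(".")[1]
    s = re.sub(r"[^A-Za-z]", "", s)
    return s.upper()


def gene_of(accession: str) -> str:
    """Gene locus of an Araport11-style ``GENE.ISOFORM`` accession."""
    return accession.rsplit(".", 1)[0] if "." in accession else accession


@dataclass(frozen=True)
class PeptideRecord:
    sequence: str
    engines: frozenset[str]
    matched_isoforms: frozenset[str]
    is_decoy: bool = False
    nterm_met_loss: bool = False
    protein_start: int | None = None  # 1-based residue in the matched protein(s)
    modified_forms: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(self.sequence) < 5:
            raise ValueError(f"peptide too short: {self.sequence!r}")
        if self.sequence != self.sequence.upper():
            raise ValueError("peptide sequence must be uppercase")

    @property
    def matched_genes(self) -> frozenset[str]:
        return frozenset(gene_of(a) for a in self.matched_isoforms)


@dataclass
class ColumnMap:
    """Column names of one engine's peptide table."""

    sequence: str = "peptide"
    proteins: str = "proteins"
    decoy: str | None = None  # optional boolean/int column
    protein_sep: str = ";"


#: ready-made column maps for the two supported export dialects
PROSPECTOR_COLUMNS = ColumnMap(sequence="DB Peptide", proteins="Acc #", protein_sep=";")
FRAGGER_COLUMNS = ColumnMap(sequence="Peptide", proteins="Protein", protein_sep=",")


def _is_decoy_accession(acc: str, decoy_tag: str) -> bool:
    return acc.startswith(decoy_tag) or acc.endswith(decoy_tag)


def ingest_and_merge(
    tables: Sequence[tuple[str, str | Path, ColumnMap]],
    decoy_tag: str = "DECOY_",
    known_accessions: set[str] | None = None,
    stats: dict | None = None,
) -> list[PeptideRecord]:
    """Read engine TSVs, drop decoys, and merge records on plain sequence.

    ``tables`` is a list of (engine_label, path, column_map).  Accessions
    absent from ``known_accessions`` (when given) are logged and dropped;
    a peptide whose accessions are all unknown is dropped entirely.  When a
    ``stats`` dict is passed it is filled with input/decoy/unmapped/output
    counts over distinct sequences, satisfying
    ``input == output + decoys + unmapped``.
    """
    merged: dict[str, dict] = {}
    seen: set[str] = set()
    decoy_seqs: set[str] = set()
    unmapped_seqs: set[str] = set()
    for engine, path, cmap in tables:
        df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
        for col in (cmap.sequence, cmap.proteins):
            if col not in df.columns:
                raise ValueError(f"{path}: missing column {col!r}")
        for _, row in df.iterrows():
            raw_seq = row[cmap.sequence]
            seq = strip_modifications(raw_seq)
            if not seq:
                continue
            seen.add(seq)
            accs = [a.strip() for a in row[cmap.proteins].split(cmap.protein_sep) if a.strip()]
            decoy = any(_is_decoy_accession(a, decoy_tag) for a in accs)
            if cmap.decoy and str(row.get(cmap.decoy, "")).strip().lower() in ("1", "true", "yes"):
                decoy = True
            if decoy:
                decoy_seqs.add(seq)
                continue
            if known_accessions is not None:
                unknown = [a for a in accs if a not in known_accessions]
                for a in unknown:
                    logger.warning("unknown accession %s for peptide %s; dropped", a, seq)
                accs = [a for a in accs if a in known_accessions]
            if not accs:
                logger.warning("peptide %s has no mappable accession; dropped", seq)
                unmapped_seqs.add(seq)
                continue
            entry = merged.setdefault(
                seq, {"engines": set(), "isoforms": set(), "mods": set()}
            )
            entry["engines"].add(engine)
            entry["isoforms"].update(accs)
            if raw_seq != seq:
                entry["mods"].add(raw_seq)
    records = [
        PeptideRecord(
            sequence=seq,
            engines=frozenset(v["engines"]),
            matched_isoforms=frozenset(v["isoforms"]),
            modified_forms=tuple(sorted(v["mods"])),
        )
        for seq, v in sorted(merged.items())
    ]
    if stats is not None:
        decoy_only = decoy_seqs - set(merged)
        unmapped_only = unmapped_seqs - set(merged) - decoy_only
        stats.update(
            input=len(seen),
            decoys=len(decoy_only),
            unmapped=len(unmapped_only),
            output=len(records),
        )
    return records


def _match_positions(peptide: str, protein: str, il_equivalent: bool) -> list[int]:
    if il_equivalent:
        peptide = peptide.replace("L", "J").replace("I", "J")
        protein = protein.replace("L", "J").replace("I", "J")
    out = []
    i = protein.find(peptide)
    while i != -1:
        out.append(i + 1)  # 1-based
        i = protein.find(peptide, i + 1)
    return out


def adjust_met_loss(
    p: PeptideRecord,
    proteins: Mapping[str, str],
    il_equivalent: bool = False,
) -> PeptideRecord | None:
    """Re-anchor a peptide in its proteins, applying the Met-loss rule.

    A peptide whose only anchor in a protein is residue 2 of a Met-initiated
    protein is an N-terminal match with the initiator methionine lost: the
    record is flagged ``nterm_met_loss`` with protein-coordinate start 2.
    Internal matches (position != 2) and position-1 matches never set the
    flag.  Returns None (and logs) when the peptide matches no protein.
    """
    matched: set[str] = set()
    met_loss_accs: set[str] = set()
    for acc in sorted(p.matched_isoforms):
        prot = proteins.get(acc)
        if prot is None:
            continue
        positions = _match_positions(p.sequence, prot, il_equivalent)
        if not positions:
            continue
        matched.add(acc)
        if positions == [2] and prot[:1] == "M":
            met_loss_accs.add(acc)
    if not matched:
        logger.warning("peptide %s matches no protein; excluded", p.sequence)
        return None
    if matched == met_loss_accs:
        return replace(
            p,
            matched_isoforms=frozenset(matched),
            nterm_met_loss=True,
            protein_start=2,
        )
    return replace(p, matched_isoforms=frozenset(matched), nterm_met_loss=False)


def validate_matches(
    peptides: Iterable[PeptideRecord],
    proteins: Mapping[str, str],
    il_equivalent: bool = False,
) -> list[PeptideRecord]:
    """Apply :func:`adjust_met_loss` to every record, dropping non-matchers."""
    out = []
    for p in peptides:
        adj = adjust_met_loss(p, proteins, il_equivalent)
        if adj is not None:
            out.append(adj)
    return out


@dataclass
class LocusClassification:
    category_of: dict[str, str]  # peptide sequence -> category
    supported_isoforms: dict[str, int]  # gene -> max pairwise-disjoint sets
    counts: Counter = field(default_factory=Counter)

    def peptides_in(self, category: str) -> list[str]:
        return sorted(s for s, c in self.category_of.items() if c == category)


def classify_locus(
    peptides: Sequence[PeptideRecord],
    isoforms_per_gene: Mapping[str, set[str]],
) -> LocusClassification:
    """Assign each peptide one category per the disjointness rule.

    Categories: ``multi_gene`` (maps to >1 locus, excluded),
    ``single_isoform_gene`` (locus has one isoform, excluded),
    ``shared_all_isoforms`` (maps to every isoform of its locus),
    ``isoform_specific`` (disjoint from >=1 other peptide's set at the locus),
    ``subset_unpaired`` (proper subset but no disjoint partner; diagnostic).
    """
    category: dict[str, str] = {}
    by_gene: dict[str, list[PeptideRecord]] = {}
    for p in peptides:
        if p.is_decoy:
            raise ValueError(f"decoy peptide {p.sequence} past ingestion")
        if not p.matched_isoforms:
            raise ValueError(f"peptide {p.sequence} has empty matched_isoforms")
        genes = p.matched_genes
        if len(genes) > 1:
            category[p.sequence] = "multi_gene"
            continue
        gene = next(iter(genes))
        full_set = isoforms_per_gene.get(gene, set())
        if len(full_set) <= 1:
            category[p.sequence] = "single_isoform_gene"
            continue
        by_gene.setdefault(gene, []).append(p)

    supported: dict[str, int] = {}
    for gene, ps in by_gene.items():
        full_set = frozenset(isoforms_per_gene[gene])
        sets = [p.matched_isoforms for p in ps]
        for p in ps:
            mine = p.matched_isoforms
            if mine == full_set:
                category[p.sequence] = "shared_all_isoforms"
            elif any(not (mine & other) for other in sets if other is not mine):
                category[p.sequence] = "isoform_specific"
            else:
                category[p.sequence] = "subset_unpaired"
        if any(category[p.sequence] == "isoform_specific" for p in ps):
            supported[gene] = count_supported_isoforms(sets)

    return LocusClassification(
        category_of=category,
        supported_isoforms=supported,
        counts=Counter(category.values()),
    )


def count_supported_isoforms(sets: Sequence[frozenset[str]]) -> int:
    """Maximum number of pairwise-disjoint matched-isoform sets (exact).

    Exhaustive search over distinct sets; locus isoform counts are small
    (<= ~10) so this is cheap.
    """
    uniq = sorted(set(sets), key=sorted)
    best = 0

    def extend(i: int, chosen_union: frozenset[str], n: int) -> None:
        nonlocal best
        best = max(best, n)
        for j in range(i, len(uniq)):
            if not (uniq[j] & chosen_union):
                extend(j + 1, chosen_union | uniq[j], n + 1)

    extend(0, frozenset(), 0)
    return best


def classification_table(
    peptides: Sequence[PeptideRecord], classification: LocusClassification
) -> pd.DataFrame:
    rows = []
    for p in peptides:
        rows.append(
            {
                "peptide": p.sequence,
                "category": classification.category_of.get(p.sequence, ""),
                "engines": ",".join(sorted(p.engines)),
                "matched_isoforms": ",".join(sorted(p.matched_isoforms)),
                "nterm_met_loss": p.nterm_met_loss,
            }
        )
    return pd.DataFrame(rows)


def locus_summary(classification: LocusClassification) -> pd.DataFrame:
    rows = [
        {"gene_id": g, "supported_isoform_count": n}
        for g, n in sorted(classification.supported_isoforms.items())
    ]
    return pd.DataFrame(rows, columns=["gene_id", "supported_isoform_count"])
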