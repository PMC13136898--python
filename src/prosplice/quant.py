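"""Quantitative post-processing: protein-group selection, imputation,
differential flags, increased-IR calls, and peptide-vs-intron positioning.

Imputation follows the Perseus-style convention: eligible rows (completely
missing in one condition, completely observed in the other) are filled with
draws from Normal(mu_total - shift*sd_total, (width*sd_total)^2).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _scipy_stats

from .genome_model import IntronRecord, TranscriptModel
from .ir_discovery import IntronDepthRecord
from .peptide_filter import gene_of

logger = logging.getLogger(__name__)


@dataclass
class QuantMatrix:
    """Log2 abundance matrix with a condition label per sample column."""

    values: pd.DataFrame  # rows = protein groups / peptides; cols = samples
    conditions: dict[str, str]  # sample -> condition label

    def __post_init__(self) -> None:
        missing = set(self.values.columns) - set(self.conditions)
        if missing:
            raise ValueError(f"samples without condition labels: {sorted(missing)}")
        finite = self.values.to_numpy(dtype=float)
        if np.isinf(finite[~np.isnan(finite)]).any():
            raise ValueError("non-finite observed values")

    def condition_columns(self, condition: str) -> list[str]:
        return [c for c in self.values.columns if self.conditions[c] == condition]

    @property
    def condition_labels(self) -> list[str]:
        return sorted(set(self.conditions.values()))


def select_protein_groups(
    groups: pd.DataFrame,
    accession_col: str = "accessions",
    peptide_count_col: str = "n_peptides",
    sep: str = ";",
) -> pd.DataFrame:
    """One protein group per gene locus.

    Groups whose member accessions span several gene loci are discarded;
    when several groups remain for one locus the one with the most
    quantified peptides is kept (ties: lexicographically smallest accession
    string, logged).
    """
    loci = []
    keep_rows = []
    for idx, row in groups.iterrows():
        accs = [a.strip() for a in str(row[accession_col]).split(sep) if a.strip()]
        genes = {gene_of(a) for a in accs}
        if len(genes) != 1:
            continue  # ambiguous multi-locus group
        loci.append(next(iter(genes)))
        keep_rows.append(idx)
    df = groups.loc[keep_rows].copy()
    df["_locus"] = loci
    winners = []
    for locus, sub in df.groupby("_locus"):
        if len(sub) == 1:
            winners.append(sub.index[0])
            continue
        best = sub.sort_values(
            by=[peptide_count_col, accession_col], ascending=[False, True]
        )
        if (sub[peptide_count_col] == best.iloc[0][peptide_count_col]).sum() > 1:
            logger.info(
                "locus %s: peptide-count tie; keeping %s",
                locus,
                best.iloc[0][accession_col],
            )
        winners.append(best.index[0])
    return df.loc[sorted(winners)].drop(columns="_locus")


def impute_missing(
    m: QuantMatrix,
    width: float = 0.3,
    shift: float = 1.8,
    seed: int | None = None,
    sd_units: bool = True,
) -> QuantMatrix:
    """Impute rows completely missing in one condition and complete in the other.

    With ``sd_units`` (default) width/shift are multiples of the total-matrix
    SD; otherwise they are raw log2 units.  Observed values are never
    altered; results are reproducible for a fixed seed.
    """
    labels = m.condition_labels
    if len(labels) != 2:
        raise ValueError("imputation requires exactly two conditions")
    arr = m.values.to_numpy(dtype=float)
    observed = arr[~np.isnan(arr)]
    if observed.size < 2:
        raise ValueError("need >=2 observed values to estimate the distribution")
    mu, sd = float(observed.mean()), float(observed.std(ddof=1))
    loc = mu - shift * (sd if sd_units else 1.0)
    scale = width * (sd if sd_units else 1.0)
    rng = np.random.default_rng(seed)
    out = m.values.copy()
    cols = {lab: m.condition_columns(lab) for lab in labels}
    for ridx, row in out.iterrows():
        for missing_lab, present_lab in ((labels[0], labels[1]), (labels[1], labels[0])):
            miss_cols, pres_cols = cols[missing_lab], cols[present_lab]
            if row[miss_cols].isna().all() and row[pres_cols].notna().all():
                out.loc[ridx, miss_cols] = rng.normal(loc, scale, size=len(miss_cols))
    return QuantMatrix(values=out, conditions=dict(m.conditions))


def welch_test(m: QuantMatrix) -> pd.DataFrame:
    """Two-sample Welch's t-test per row: a labeled stand-in for the external
    moderated test, producing log2FC (condition2 - condition1) and p-values."""
    a_lab, b_lab = m.condition_labels
    a = m.values[m.condition_columns(a_lab)].to_numpy(dtype=float)
    b = m.values[m.condition_columns(b_lab)].to_numpy(dtype=float)
    log2fc = np.nanmean(b, axis=1) - np.nanmean(a, axis=1)
    pvals = []
    for i in range(a.shape[0]):
        x, y = a[i][~np.isnan(a[i])], b[i][~np.isnan(b[i])]
        if len(x) < 2 or len(y) < 2:
            pvals.append(np.nan)
            continue
        pvals.append(_scipy_stats.ttest_ind(y, x, equal_var=False).pvalue)
    return pd.DataFrame(
        {"log2fc": log2fc, "pvalue": pvals, "method": "welch_standin"},
        index=m.values.index,
    )


def call_differential(
    table: pd.DataFrame,
    p_cut: float = 0.05,
    lfc_cut: float = 1.0,
    lfc_col: str = "log2fc",
    p_col: str = "pvalue",
) -> pd.DataFrame:
    """Flag rows with p < p_cut and |log2FC| > lfc_cut.

    Rows with missing p-values are removed first.
    """
    df = table.dropna(subset=[p_col]).copy()
    df["differential"] = (df[p_col] < p_cut) & (df[lfc_col].abs() > lfc_cut)
    return df


@dataclass(frozen=True)
class IIRCall:
    gene_id: str
    intron: IntronRecord
    region: str  # 5UTR | CDS | 3UTR
    ir_depth_wt: float
    ir_depth_mut: float
    fold_change: float
    is_iir: bool
    floored_wt: bool = False


def _intron_region(
    intron: IntronRecord, transcripts: Sequence[TranscriptModel]
) -> str:
    """5UTR/CDS/3UTR by intron position against the gene's CDS span."""
    spans = [
        t.cds_span for t in transcripts if t.gene_id == intron.gene_id and t.cds_span
    ]
    if not spans:
        return "CDS"
    lo = min(s for s, _ in spans)
    hi = max(e for _, e in spans)
    s, e = intron.interval
    if e <= lo:
        genomic_left = True
    elif s >= hi:
        genomic_left = False
    else:
        return "CDS"
    if intron.strand == "+":
        return "5UTR" if genomic_left else "3UTR"
    return "3UTR" if genomic_left else "5UTR"


def call_iir(
    wt_records: Sequence[IntronDepthRecord],
    mut_records: Sequence[IntronDepthRecord],
    transcripts: Sequence[TranscriptModel],
    depth_cut: float = 0.15,
    fold_cut: float = 1.5,
    wt_floor: float = 0.01,
) -> list[IIRCall]:
    """Increased-IR calls: mutant IDratio >= depth_cut and fold >= fold_cut.

    Replicate records are averaged per intron; zero WT depth is floored at
    ``wt_floor`` (flagged) before the ratio.
    """

    def mean_by_intron(records: Sequence[IntronDepthRecord]) -> dict[tuple, tuple[IntronRecord, float]]:
        acc: dict[tuple, list[float]] = {}
        obj: dict[tuple, IntronRecord] = {}
        for r in records:
            if not r.is_defined:
                continue
            key = (r.intron.chrom, r.intron.interval, r.intron.gene_id)
            acc.setdefault(key, []).append(r.idratio)
            obj[key] = r.intron
        return {k: (obj[k], sum(v) / len(v)) for k, v in acc.items()}

    wt = mean_by_intron(wt_records)
    mut = mean_by_intron(mut_records)
    calls = []
    for key in sorted(mut):
        intron, mut_ratio = mut[key]
        wt_ratio = wt.get(key, (None, 0.0))[1]
        floored = wt_ratio < wt_floor
        denom = max(wt_ratio, wt_floor)
        fold = mut_ratio / denom
        # tolerate float error at the printed thresholds (e.g. 0.15/0.10)
        passes_depth = mut_ratio >= depth_cut or math.isclose(mut_ratio, depth_cut, rel_tol=1e-9)
        passes_fold = fold >= fold_cut or math.isclose(fold, fold_cut, rel_tol=1e-9)
        is_iir = passes_depth and passes_fold
        calls.append(
            IIRCall(
                gene_id=intron.gene_id,
                intron=intron,
                region=_intron_region(intron, transcripts),
                ir_depth_wt=wt_ratio,
                ir_depth_mut=mut_ratio,
                fold_change=fold,
                is_iir=is_iir,
                floored_wt=floored,
            )
        )
    return calls


def intron_insertion_aa(intron: IntronRecord, t: TranscriptModel) -> int | None:
    """Amino-acid position of the intron insertion in the isoform's protein.

    Position = ceil((cumulative CDS nt upstream of the intron + 1) / 3);
    None when the intron junction is not inside the CDS of the isoform.
    """
    s, e = intron.interval
    span = t.cds_span
    if span is None or not (span[0] < s and e < span[1]):
        return None
    if t.strand == "+":
        upstream = sum(b - a for a, b in t.cds_segments if b <= s)
    else:
        upstream = sum(b - a for a, b in t.cds_segments if a >= e)
    return math.ceil((upstream + 1) / 3)


def annotate_peptide_vs_intron(
    protein_start: int,
    protein_end: int,
    intron: IntronRecord,
    t: TranscriptModel,
) -> str:
    """Classify a peptide's protein interval vs the intron insertion point:
    upstream / downstream / spanning / not_applicable."""
    pos = intron_insertion_aa(intron, t)
    if pos is None:
        return "not_applicable"
    if protein_end < pos:
        return "upstream"
    if protein_start > pos:
        return "downstream"
    return "spanning"


def iir_table(calls: Iterable[IIRCall]) -> pd.DataFrame:
    rows = [
        {
            "gene_id": c.gene_id,
            "chrom": c.intron.chrom,
            "start": c.intron.interval[0],
            "end": c.intron.interval[1],
            "strand": c.intron.strand,
            "region": c.region,
            "ir_depth_wt": c.ir_depth_wt,
            "ir_depth_mut": c.ir_depth_mut,
            "fold_change": c.fold_change,
            "is_iir": c.is_iir,
        }
        for c in calls
    ]
    return pd.DataFrame(rows)
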