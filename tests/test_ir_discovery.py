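import math
import random

import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from prosplice.as_events import generate_events
from prosplice.genome_model import GenomeSequence, TranscriptModel, enumerate_introns
from prosplice.ir_discovery import (
    CustomProteinEntry,
    build_candidate_entries,
    build_ir_protein,
    compute_idratio,
    fit_intron_to_transcripts,
    read_region_depths,
    select_candidates,
    summarize_outcomes,
    write_custom_database,
)


def _three_exon_t(strand="+"):
    return TranscriptModel(
        "G.1", "G", "c", strand,
        exons=((100, 200), (300, 400), (500, 600)),
        cds_segments=((100, 200), (300, 400), (500, 600)),
        protein_sequence="X" * 100,
    )


def _depth_frame(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "sample", "mean_depth"])


def _depths_for(t, intron_depths, exon_depths, sample="s1"):
    rows = []
    for iv, d in zip(
        [(t.exons[i][1], t.exons[i + 1][0]) for i in range(len(t.exons) - 1)],
        intron_depths,
    ):
        rows.append(("c", iv[0], iv[1], sample, d))
    for ex, d in zip(t.exons, exon_depths):
        rows.append(("c", ex[0], ex[1], sample, d))
    return _depth_frame(rows)


class TestComputeIdratio:
    def test_internal_intron_uses_both_flanks(self):
        # 4-exon transcript so the middle intron is non-terminal
        t = TranscriptModel(
            "G.1", "G", "c", "+",
            exons=((0, 100), (200, 300), (400, 500), (600, 700)),
            cds_segments=(),
        )
        depths = _depths_for(t, [1, 5, 1], [10, 40, 60, 10])
        recs = compute_idratio(depths, enumerate_introns(t), {"G.1": t})
        mid = next(r for r in recs if r.intron.plus_strand_index == 2)
        assert mid.idratio == pytest.approx(5 / ((40 + 60) / 2), abs=1e-12)
        assert not mid.terminal_rule_applied

    def test_first_intron_uses_only_second_exon(self):
        t = _three_exon_t()
        depths = _depths_for(t, [6, 1], [999, 40, 10])
        recs = compute_idratio(depths, enumerate_introns(t), {"G.1": t})
        first = next(r for r in recs if r.intron.plus_strand_index == 1)
        assert first.idratio == pytest.approx(0.15, abs=1e-12)
        assert first.terminal_rule_applied

    def test_last_intron_uses_only_internal_exon(self):
        t = _three_exon_t()
        depths = _depths_for(t, [1, 8], [10, 40, 999])
        recs = compute_idratio(depths, enumerate_introns(t), {"G.1": t})
        last = next(r for r in recs if r.intron.plus_strand_index == 2)
        assert last.idratio == pytest.approx(8 / 40, abs=1e-12)
        assert last.terminal_rule_applied

    def test_zero_intron_depth(self):
        t = _three_exon_t()
        depths = _depths_for(t, [0, 1], [10, 40, 10])
        recs = compute_idratio(depths, enumerate_introns(t), {"G.1": t})
        assert next(r.idratio for r in recs if r.intron.plus_strand_index == 1) == 0.0

    def test_zero_exon_depth_undefined(self):
        t = _three_exon_t()
        depths = _depths_for(t, [5, 1], [10, 0, 10])
        recs = compute_idratio(depths, enumerate_introns(t), {"G.1": t})
        assert not next(r for r in recs if r.intron.plus_strand_index == 1).is_defined

    def test_missing_intron_depth_flagged(self):
        t = _three_exon_t()
        depths = _depths_for(t, [5], [10, 40, 10])  # second intron absent
        recs = compute_idratio(depths, enumerate_introns(t), {"G.1": t})
        missing = next(r for r in recs if r.intron.plus_strand_index == 2)
        assert not missing.is_defined and math.isnan(missing.intron_depth)

    @given(st.floats(min_value=0.01, max_value=1000.0))
    @settings(max_examples=30, deadline=None)
    def test_scale_invariance(self, c):
        t = _three_exon_t()
        base = _depths_for(t, [5, 7], [10, 40, 30])
        scaled = base.copy()
        scaled["mean_depth"] = scaled["mean_depth"] * c
        r1 = compute_idratio(base, enumerate_introns(t), {"G.1": t})
        r2 = compute_idratio(scaled, enumerate_introns(t), {"G.1": t})
        for a, b in zip(r1, r2):
            assert a.idratio == pytest.approx(b.idratio, rel=1e-9)


class TestSelectCandidates:
    def _records(self, wt, mut):
        t = _three_exon_t()
        frames = [_depths_for(t, [wt * 40, 0], [999, 40, 10], "wt1"),
                  _depths_for(t, [mut * 40, 0], [999, 40, 10], "mut1")]
        depths = pd.concat(frames, ignore_index=True)
        return compute_idratio(depths, enumerate_introns(t), {"G.1": t})

    def test_either_group_semantics(self):
        recs = self._records(wt=0.16, mut=0.01)
        sel = select_candidates(recs, [], sample_groups={"WT": ["wt1"], "mut": ["mut1"]})
        assert [c.interval for c in sel] == [(200, 300)]

    def test_threshold_inclusive(self):
        recs = self._records(wt=0.15, mut=0.01)
        assert select_candidates(recs, []) != []

    def test_below_threshold_excluded(self):
        recs = self._records(wt=0.1499, mut=0.1499)
        assert select_candidates(recs, []) == []

    def test_annotated_ri_excluded(self):
        recs = self._records(wt=0.30, mut=0.30)
        t = _three_exon_t()
        retained = TranscriptModel(
            "G.2", "G", "c", "+", exons=((100, 400), (500, 600)),
        )
        events = generate_events([t, retained], types=("RI",))
        assert len(events) == 1
        assert select_candidates(recs, events) == []

    def test_monotone_in_threshold(self):
        rng = random.Random(0)
        t = _three_exon_t()
        frames = []
        for s in ("a", "b", "c"):
            frames.append(
                _depths_for(
                    t,
                    [rng.uniform(0, 30), rng.uniform(0, 30)],
                    [rng.uniform(50, 150)] * 3,
                    s,
                )
            )
        recs = compute_idratio(pd.concat(frames, ignore_index=True),
                               enumerate_introns(t), {"G.1": t})
        sizes = [
            len(select_candidates(recs, [], threshold=th))
            for th in (0.01, 0.05, 0.1, 0.2, 0.4, 0.8)
        ]
        assert sizes == sorted(sizes, reverse=True)


class TestFitIntron:
    def test_internal_fit(self):
        t = _three_exon_t()
        assert fit_intron_to_transcripts((200, 300), [t]) == [(t, "internal")]

    def test_one_nt_gap_rejected(self):
        t = _three_exon_t()
        assert fit_intron_to_transcripts((201, 300), [t]) == []
        assert fit_intron_to_transcripts((200, 299), [t]) == []

    def test_terminal_modes_flagged(self):
        t = _three_exon_t()
        assert fit_intron_to_transcripts((50, 100), [t]) == [(t, "upstream")]
        assert fit_intron_to_transcripts((600, 650), [t]) == [(t, "downstream")]


class TestBuildIrProtein:
    def test_inframe_81nt_adds_27aa(self, models_by_id, genome, fx):
        t = models_by_id["AT1G00010.1"]
        intron = next(i for i in enumerate_introns(t) if i.plus_strand_index == 1)
        entry = build_ir_protein(t, intron.interval, genome)
        assert entry.outcome == "extended_in_frame"
        assert entry.delta_length_aa == 27 == intron.length // 3
        assert entry.accession == "AT1G00010.1_IR1"
        # the in-frame IR protein equals the annotated retained isoform
        assert entry.protein_sequence == models_by_id["AT1G00010.2"].protein_sequence

    def test_early_stop_truncates_after_4_intronic_aa(self, models_by_id, genome):
        t = models_by_id["AT1G00020.1"]
        intron = enumerate_introns(t)[0]
        entry = build_ir_protein(t, intron.interval, genome)
        assert entry.outcome == "truncated"
        # upstream CDS (30 aa) + 4 intronic residues
        assert len(entry.protein_sequence) == 34
        assert entry.protein_sequence[:30] == t.protein_sequence[:30]

    def test_frameshift_extension(self, models_by_id, genome, fx):
        t = models_by_id["AT2G00040.1"]
        intron = enumerate_introns(t)[0]
        entry = build_ir_protein(t, intron.interval, genome)
        assert entry.outcome == "frameshift_extended"
        truth = fx.manifest.ir["entries"]["AT2G00040.1_IR1"]
        assert entry.protein_sequence == truth["protein"]
        assert entry.delta_length_aa == truth["delta"]

    def test_utr_intron_flagged_non_cds(self, models_by_id, genome):
        t = models_by_id["AT2G00060.1"]
        intron = enumerate_introns(t)[0]
        entry = build_ir_protein(t, intron.interval, genome)
        assert not entry.in_cds
        assert entry.protein_sequence == t.protein_sequence

    def test_entry_never_contains_stop(self):
        with pytest.raises(ValueError):
            CustomProteinEntry(
                accession="A.1_IR1", base_transcript_id="A.1",
                retained_intron=(0, 3), protein_sequence="MA*",
                outcome="truncated", delta_length_aa=-1,
            )


class TestOutcomesAndDatabase:
    def test_summarize_outcomes_fractions(self):
        def entry(acc, outcome, delta):
            return CustomProteinEntry(
                accession=acc, base_transcript_id="b", retained_intron=(0, 3),
                protein_sequence="MA", outcome=outcome, delta_length_aa=delta,
            )

        entries = [
            entry("a", "truncated", -5),
            entry("b", "truncated", -3),
            entry("c", "truncated", -1),
            entry("d", "extended_in_frame", 9),
        ]
        tab = summarize_outcomes({"set1": entries}).set_index("set")
        assert tab.loc["set1", "truncated_fraction"] == pytest.approx(0.75)

    def test_summarize_empty_and_all_inframe(self):
        assert summarize_outcomes({"empty": []}).empty

        e = CustomProteinEntry(
            accession="a", base_transcript_id="b", retained_intron=(0, 3),
            protein_sequence="MA", outcome="extended_in_frame", delta_length_aa=1,
        )
        tab = summarize_outcomes({"s": [e]}).set_index("set")
        assert tab.loc["s", "truncated_fraction"] == 0.0

    def _base(self, tmp_path, n=10):
        p = tmp_path / "base.fa"
        with open(p, "w") as fh:
            for i in range(n):
                fh.write(f">B.{i}\nMKKK{'A' * i}\n")
        return p

    def _entry(self, acc, seq):
        return CustomProteinEntry(
            accession=acc, base_transcript_id="b", retained_intron=(0, 3),
            protein_sequence=seq, outcome="extended_in_frame", delta_length_aa=1,
        )

    def test_append_two_entries(self, tmp_path):
        base = self._base(tmp_path)
        out = tmp_path / "out.fa"
        n = write_custom_database(base, [self._entry("X.1_IR1", "MWWW"),
                                         self._entry("X.2_IR1", "MYYY")], out)
        assert n == 12
        assert out.read_text().count(">") == 12

    def test_duplicate_sequence_dropped(self, tmp_path, caplog):
        base = self._base(tmp_path)
        out = tmp_path / "out.fa"
        n = write_custom_database(base, [self._entry("X.1_IR1", "MKKK")], out)
        assert n == 10

    def test_empty_entries_byte_identical(self, tmp_path):
        base = self._base(tmp_path)
        out = tmp_path / "out.fa"
        write_custom_database(base, [], out)
        assert out.read_bytes() == base.read_bytes()

    def test_accession_collision_hard_error(self, tmp_path):
        base = self._base(tmp_path)
        with pytest.raises(ValueError, match="collision"):
            write_custom_database(base, [self._entry("B.1", "MWWW")], tmp_path / "o.fa")


class TestFixturePipeline:
    def test_candidates_and_entries_match_manifest(self, fixture_dir, fx, models, genome):
        by_id = {t.transcript_id: t for t in models}
        introns = [i for t in models for i in enumerate_introns(t)]
        records = compute_idratio(
            read_region_depths(fixture_dir / "coverage.tsv"), introns, by_id
        )
        groups = {"WT": list(fx.spec.wt_samples), "mut": list(fx.spec.mut_samples)}
        events = generate_events(models, types=("RI",))
        selected = select_candidates(records, events, sample_groups=groups)
        assert {(c.gene_id, c.interval) for c in selected} == {
            (c["gene_id"], tuple(c["interval"])) for c in fx.manifest.ir["candidates"]
        }
        entries = build_candidate_entries(selected, models, genome)
        truth = fx.manifest.ir["entries"]
        assert {e.accession for e in entries} == set(truth)
        for e in entries:
            t = truth[e.accession]
            assert (e.outcome, e.delta_length_aa, e.in_cds, e.protein_sequence) == (
                t["outcome"], t["delta"], t["in_cds"], t["protein"],
            )

    def test_inframe_delta_equals_length_over_three(self, models, genome):
        # every frame-preserving stop-free fixture intron obeys delta == len/3
        for t in models:
            if not t.cds_segments:
                continue
            for intron in enumerate_introns(t):
                entry = build_ir_protein(t, intron.interval, genome)
                if entry.outcome == "extended_in_frame" and entry.in_cds:
                    assert entry.delta_length_aa == intron.length // 3
                    assert intron.length % 3 == 0

    def test_ir_proteins_reproducible_from_genome(self, models, genome):
        # independent oracle: splice CDS+intron from raw chromosome string
        from prosplice.genome_model import reverse_complement, translate_cds

        for t in models:
            if len(t.cds_segments) < 2:
                continue
            for intron in enumerate_introns(t):
                entry = build_ir_protein(t, intron.interval, genome)
                if not entry.in_cds:
                    continue
                segs = sorted(list(t.cds_segments) + [intron.interval])
                raw = "".join(genome[t.chrom].sequence[s:e] for s, e in segs)
                if t.strand == "-":
                    raw = reverse_complement(raw)
                assert entry.protein_sequence == translate_cds(raw, "+")
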