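import itertools

import pytest
from hypothesis import given, settings, strategies as st

from prosplice.peptide_filter import (
    FRAGGER_COLUMNS,
    PROSPECTOR_COLUMNS,
    PeptideRecord,
    adjust_met_loss,
    classify_locus,
    count_supported_isoforms,
    ingest_and_merge,
    strip_modifications,
    validate_matches,
)


def _rec(seq, isoforms, **kw):
    return PeptideRecord(
        sequence=seq, engines=frozenset({"e1"}), matched_isoforms=frozenset(isoforms), **kw
    )


class TestStripModifications:
    @pytest.mark.parametrize(
        "raw,plain",
        [
            ("PEPTIDE", "PEPTIDE"),
            ("PEPT(ox)IDE", "PEPTIDE"),
            ("M[15.9949]PEPTIDE", "MPEPTIDE"),
            ("K.PEPTIDER.A", "PEPTIDER"),
            ("peptIDE", "PEPTIDE"),
            ("PEP{Cam}TIDE", "PEPTIDE"),
        ],
    )
    def test_cases(self, raw, plain):
        assert strip_modifications(raw) == plain


class TestIngestAndMerge:
    def _write(self, path, rows, prospector=True):
        if prospector:
            lines = ["DB Peptide\tAcc #"] + [f"{s}\t{a}" for s, a in rows]
        else:
            lines = ["Peptide\tProtein"] + [f"{s}\t{a}" for s, a in rows]
        path.write_text("\n".join(lines) + "\n")

    def test_merge_two_engines_same_peptide(self, tmp_path):
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        self._write(p1, [("PEPTIDEK", "G1.1;G1.2")])
        self._write(p2, [("PEPTIDEK", "G1.1,G1.2")], prospector=False)
        recs = ingest_and_merge(
            [("e1", p1, PROSPECTOR_COLUMNS), ("e2", p2, FRAGGER_COLUMNS)]
        )
        assert len(recs) == 1
        assert recs[0].engines == {"e1", "e2"}
        assert recs[0].matched_isoforms == {"G1.1", "G1.2"}

    def test_decoy_removed_and_counting_identity(self, tmp_path):
        p = tmp_path / "a.tsv"
        self._write(
            p,
            [
                ("PEPTIDEK", "G1.1"),
                ("AAAAAAK", "DECOY_G1.1"),
                ("CCCCCCK", "G2.1"),
            ],
        )
        stats = {}
        recs = ingest_and_merge([("e1", p, PROSPECTOR_COLUMNS)], stats=stats)
        assert {r.sequence for r in recs} == {"PEPTIDEK", "CCCCCCK"}
        assert stats["input"] == stats["output"] + stats["decoys"] + stats["unmapped"]
        assert stats == {"input": 3, "decoys": 1, "unmapped": 0, "output": 2}

    def test_unknown_accession_dropped(self, tmp_path):
        p = tmp_path / "a.tsv"
        self._write(p, [("PEPTIDEK", "G1.1;GHOST.9"), ("DDDDDDK", "GHOST.9")])
        stats = {}
        recs = ingest_and_merge(
            [("e1", p, PROSPECTOR_COLUMNS)],
            known_accessions={"G1.1"},
            stats=stats,
        )
        assert len(recs) == 1
        assert recs[0].matched_isoforms == {"G1.1"}
        assert stats["unmapped"] == 1

    def test_empty_input(self, tmp_path):
        p = tmp_path / "a.tsv"
        self._write(p, [])
        assert ingest_and_merge([("e1", p, PROSPECTOR_COLUMNS)]) == []

    def test_modified_forms_dedup_to_plain_sequence(self, tmp_path):
        p = tmp_path / "a.tsv"
        self._write(p, [("PEPT(ox)IDEK", "G1.1"), ("PEPTIDEK", "G1.1")])
        recs = ingest_and_merge([("e1", p, PROSPECTOR_COLUMNS)])
        assert len(recs) == 1
        assert recs[0].modified_forms == ("PEPT(ox)IDEK",)


class TestMetLoss:
    PROTS = {"P.1": "MAVLKQWERTY", "P.2": "GGGGGAVLKQGGG"}

    def test_nterm_met_loss_flagged(self):
        rec = adjust_met_loss(_rec("AVLKQ", ["P.1"]), self.PROTS)
        assert rec.nterm_met_loss and rec.protein_start == 2
        assert rec.matched_isoforms == {"P.1"}

    def test_position_one_match_not_flagged(self):
        rec = adjust_met_loss(_rec("MAVLK", ["P.1"]), self.PROTS)
        assert not rec.nterm_met_loss

    def test_internal_match_not_flagged(self):
        rec = adjust_met_loss(_rec("AVLKQ", ["P.2"]), self.PROTS)
        assert not rec.nterm_met_loss

    def test_mixed_anchor_not_flagged(self):
        rec = adjust_met_loss(_rec("AVLKQ", ["P.1", "P.2"]), self.PROTS)
        assert not rec.nterm_met_loss
        assert rec.matched_isoforms == {"P.1", "P.2"}

    def test_no_match_excluded(self):
        assert adjust_met_loss(_rec("WWWWW", ["P.1"]), self.PROTS) is None

    def test_il_equivalent_switch(self):
        prots = {"P.1": "MAVIKQWERTY"}
        assert adjust_met_loss(_rec("AVLKQ", ["P.1"]), prots) is None
        rec = adjust_met_loss(_rec("AVLKQ", ["P.1"]), prots, il_equivalent=True)
        assert rec is not None and rec.nterm_met_loss


ISOFORMS = {"G": {"G.A", "G.B"}, "H": {"H.A"}, "K": {"K.A", "K.B", "K.C"}}


class TestClassifyLocus:
    def test_disjoint_pair_specific_and_shared(self):
        peps = [
            _rec("AAAAA", ["G.A"]),
            _rec("CCCCC", ["G.B"]),
            _rec("DDDDD", ["G.A", "G.B"]),
        ]
        cls = classify_locus(peps, ISOFORMS)
        assert cls.category_of == {
            "AAAAA": "isoform_specific",
            "CCCCC": "isoform_specific",
            "DDDDD": "shared_all_isoforms",
        }

    def test_all_shared_none_specific(self):
        peps = [_rec("AAAAA", ["G.A", "G.B"]), _rec("CCCCC", ["G.A", "G.B"])]
        cls = classify_locus(peps, ISOFORMS)
        assert set(cls.category_of.values()) == {"shared_all_isoforms"}

    def test_multi_gene_excluded(self):
        peps = [_rec("AAAAA", ["G.A", "H.A"])]
        cls = classify_locus(peps, ISOFORMS)
        assert cls.category_of == {"AAAAA": "multi_gene"}

    def test_single_isoform_gene(self):
        cls = classify_locus([_rec("AAAAA", ["H.A"])], ISOFORMS)
        assert cls.category_of == {"AAAAA": "single_isoform_gene"}

    def test_subset_without_disjoint_partner(self):
        # {A,B} and {B,C} intersect; neither equals the full {A,B,C} set
        peps = [_rec("AAAAA", ["K.A", "K.B"]), _rec("CCCCC", ["K.B", "K.C"])]
        cls = classify_locus(peps, ISOFORMS)
        assert set(cls.category_of.values()) == {"subset_unpaired"}

    def test_empty_matched_isoforms_is_error(self):
        bad = PeptideRecord("AAAAA", frozenset({"e1"}), frozenset())
        with pytest.raises(ValueError):
            classify_locus([bad], ISOFORMS)

    def test_decoy_past_ingestion_is_error(self):
        bad = _rec("AAAAA", ["G.A"], is_decoy=True)
        with pytest.raises(ValueError):
            classify_locus([bad], ISOFORMS)


class TestCountSupportedIsoforms:
    @pytest.mark.parametrize(
        "sets,expected",
        [
            ([{"A"}, {"B"}, {"A", "B"}], 2),
            ([{"A"}, {"B"}, {"C"}], 3),
            ([{"A", "B"}], 1),
            ([{"A", "B"}, {"B", "C"}, {"C", "D"}], 2),
        ],
    )
    def test_examples(self, sets, expected):
        assert count_supported_isoforms([frozenset(s) for s in sets]) == expected

    @given(
        st.lists(
            st.frozensets(st.sampled_from("ABCDEF"), min_size=1, max_size=4),
            min_size=1,
            max_size=8,
        ),
        st.frozensets(st.sampled_from("ABCDEF"), min_size=1, max_size=4),
    )
    def test_monotone_under_adding_peptides(self, sets, extra):
        assert count_supported_isoforms(sets + [extra]) >= count_supported_isoforms(sets)

    def test_exhaustive_oracle_small(self):
        # compare against brute-force subset enumeration
        import random

        rng = random.Random(7)
        for _ in range(50):
            sets = [
                frozenset(rng.sample("ABCDE", rng.randint(1, 3)))
                for _ in range(rng.randint(1, 6))
            ]
            best = 0
            for r in range(1, len(sets) + 1):
                for combo in itertools.combinations(set(sets), r):
                    if all(
                        not (x & y) for x, y in itertools.combinations(combo, 2)
                    ):
                        best = max(best, r)
            assert count_supported_isoforms(sets) == best


def _brute_force_categories(peps, isoforms_per_gene):
    """O(n^2) oracle for the disjointness rule."""
    out = {}
    for p in peps:
        genes = {a.rsplit(".", 1)[0] for a in p.matched_isoforms}
        if len(genes) > 1:
            out[p.sequence] = "multi_gene"
            continue
        gene = next(iter(genes))
        full = isoforms_per_gene[gene]
        if len(full) <= 1:
            out[p.sequence] = "single_isoform_gene"
        elif p.matched_isoforms == frozenset(full):
            out[p.sequence] = "shared_all_isoforms"
        else:
            partners = [
                q
                for q in peps
                if q is not p
                and {a.rsplit(".", 1)[0] for a in q.matched_isoforms} == {gene}
            ]
            if any(not (p.matched_isoforms & q.matched_isoforms) for q in partners):
                out[p.sequence] = "isoform_specific"
            else:
                out[p.sequence] = "subset_unpaired"
    return out


@settings(max_examples=100, deadline=None)
@given(st.data())
def test_classify_matches_brute_force(data):
    n_iso = data.draw(st.integers(2, 6))
    isoforms = {f"G.{i}" for i in range(n_iso)}
    n_pep = data.draw(st.integers(1, 20))
    peps = []
    for i in range(n_pep):
        matched = data.draw(
            st.frozensets(st.sampled_from(sorted(isoforms)), min_size=1)
        )
        peps.append(_rec(f"PEP{i:03d}A", matched))
    table = {"G": isoforms}
    cls = classify_locus(peps, table)
    assert cls.category_of == _brute_force_categories(peps, table)


def test_partition_conservation(fx, fixture_dir, proteins, models):
    from prosplice.genome_model import transcripts_by_gene

    stats = {}
    recs = ingest_and_merge(
        [
            ("prospector", fixture_dir / "peptides_prospector.tsv", PROSPECTOR_COLUMNS),
            ("fragger", fixture_dir / "peptides_fragger.tsv", FRAGGER_COLUMNS),
        ],
        known_accessions=set(proteins),
        stats=stats,
    )
    recs = validate_matches(recs, proteins)
    isoforms_per_gene = {
        g: {t.transcript_id for t in ts} for g, ts in transcripts_by_gene(models).items()
    }
    cls = classify_locus(recs, isoforms_per_gene)
    assert sum(cls.counts.values()) == len(recs) == stats["output"]
    assert stats["input"] == stats["output"] + stats["decoys"] + stats["unmapped"]


def test_fixture_categories_match_manifest(fx, fixture_dir, proteins, models):
    from prosplice.genome_model import transcripts_by_gene

    recs = ingest_and_merge(
        [
            ("prospector", fixture_dir / "peptides_prospector.tsv", PROSPECTOR_COLUMNS),
            ("fragger", fixture_dir / "peptides_fragger.tsv", FRAGGER_COLUMNS),
        ],
        known_accessions=set(proteins),
    )
    recs = validate_matches(recs, proteins)
    isoforms_per_gene = {
        g: {t.transcript_id for t in ts} for g, ts in transcripts_by_gene(models).items()
    }
    cls = classify_locus(recs, isoforms_per_gene)
    expected = {p["sequence"]: p["category"] for p in fx.manifest.peptides}
    assert cls.category_of == expected
    met = {r.sequence for r in recs if r.nterm_met_loss}
    assert met == {p["sequence"] for p in fx.manifest.peptides if p["met_loss"]}
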