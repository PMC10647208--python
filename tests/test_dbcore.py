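"""Database construction, filtering, SA grouping, merging, summary."""

import json

import pytest

from asvdb import (AsvDatabase, DbEntry, build_database, filter_taxa,
                   generate, make_sa_groups, merge, summarize)
from asvdb.fixtures import FixtureSpec


def db_from(mapping, genus="Fusarium"):
    """{seq: iterable-of-taxa} -> AsvDatabase (accessions synthesized)."""
    db = AsvDatabase(genus=genus)
    for i, (seq, taxa) in enumerate(mapping.items()):
        db.entries[seq] = DbEntry(sequence=seq, taxa=set(taxa),
                                  source_accessions={f"ACC{i}"})
    return db


class TestBuildDatabase:
    def test_planted_sharing_and_collapse(self, ef1a_primers, small_fixture):
        spec, fx = small_fixture
        db = build_database(fx.records, genus="Fusarium", primers=ef1a_primers)
        # 3 species inserts + 1 shared insert + 1 'Fusarium sp.' insert
        assert len(db.entries) == spec.n_species + spec.n_shared_amplicons + 1
        multi = [e for e in db.entries.values() if len(e.taxa) >= 2]
        assert len(multi) == 1 and len(multi[0].taxa) == 2

    def test_same_species_same_amplicon_collapses(self, ef1a_primers, small_fixture):
        _, fx = small_fixture
        db = build_database(fx.records, genus="Fusarium", primers=ef1a_primers)
        two_record_entries = [e for e in db.entries.values()
                              if len(e.source_accessions) >= 2 and len(e.taxa) == 1]
        assert two_record_entries, "redundant amplicons must collapse to one entry"

    def test_off_genus_records_excluded_and_counted(self, ef1a_primers, small_fixture):
        _, fx = small_fixture
        db = build_database(fx.records, genus="Fusarium", primers=ef1a_primers)
        n_offgenus = sum(1 for p in fx.planted if p.genus != "Fusarium")
        assert n_offgenus > 0
        assert db.filter_log[0]["n_off_genus"] == n_offgenus
        all_taxa = set().union(*(e.taxa for e in db.entries.values()))
        assert all(t.startswith("Fusarium ") for t in all_taxa)

    def test_genus_match_case_insensitive(self, ef1a_primers, small_fixture):
        _, fx = small_fixture
        db = build_database(fx.records, genus="  fusarium ", primers=ef1a_primers)
        assert len(db.entries) > 0

    def test_zero_amplifiable_returns_empty_not_error(self, ef1a_primers, small_fixture):
        _, fx = small_fixture
        db = build_database(fx.records, genus="Nosuchgenus", primers=ef1a_primers)
        assert db.entries == {}
        assert db.last_emptying_stage() == "build"

    def test_empty_genus_rejected(self, ef1a_primers):
        with pytest.raises(ValueError):
            build_database([], genus="  ", primers=ef1a_primers)


class TestFilterTaxa:
    def test_sp_label_removed_entry_kept(self):
        db = db_from({"ACGT": {"Fusarium sp.", "Fusarium solani"}})
        out = filter_taxa(db)
        assert out.entries["ACGT"].taxa == {"Fusarium solani"}

    def test_entry_deleted_when_taxa_empty(self):
        db = db_from({"ACGT": {"Fusarium sp."}, "GGTT": {"Fusarium solani"}})
        out = filter_taxa(db)
        assert set(out.entries) == {"GGTT"}
        assert out.filter_log[-1]["n_entries_deleted"] == 1

    @pytest.mark.parametrize("label", ["Fusarium aff. solani", "Fusarium cf. solani"])
    def test_aff_and_cf_defaults(self, label):
        out = filter_taxa(db_from({"ACGT": {label}}))
        assert out.entries == {}

    def test_no_patterns_is_identity(self):
        db = db_from({"ACGT": {"Fusarium sp."}})
        out = filter_taxa(db, exclude_patterns=())
        assert set(out.entries) == {"ACGT"}

    def test_never_increases_taxa(self, ef1a_primers, small_fixture):
        _, fx = small_fixture
        db = build_database(fx.records, genus="Fusarium", primers=ef1a_primers)
        out = filter_taxa(db)
        for seq, entry in out.entries.items():
            assert entry.taxa <= db.entries[seq].taxa


class TestMakeSaGroups:
    def test_sa_iff_multiple_taxa(self):
        db = make_sa_groups(db_from({
            "CCCC": {"Fusarium solani"},
            "AAAA": {"Fusarium oxysporum", "Fusarium solani"},
        }))
        assert db.entries["AAAA"].assigned_name == "Fusarium_SA1"
        assert db.entries["CCCC"].assigned_name == "Fusarium_solani"
        assert [g.n for g in db.sa_groups] == [1]

    def test_numbering_lexicographic_by_sequence(self):
        db = make_sa_groups(db_from({
            "TTTT": {"Fusarium a1", "Fusarium a2"},
            "AAAA": {"Fusarium b1", "Fusarium b2"},
            "GGGG": {"Fusarium solani"},
        }))
        assert db.entries["AAAA"].assigned_name == "Fusarium_SA1"
        assert db.entries["TTTT"].assigned_name == "Fusarium_SA2"

    def test_complex_name_preserved_in_assigned_name(self):
        db = make_sa_groups(db_from({"AAAA": {"Fusarium tricinctum complex"}}))
        assert db.entries["AAAA"].assigned_name == "Fusarium_tricinctum_complex"

    def test_complex_members_form_sa(self):
        # mirrors a 2-member group of a complex plus a plain species
        db = make_sa_groups(db_from({
            "AAAA": {"Fusarium incarnatum-equiseti complex",
                     "Fusarium sporotrichioides"}}))
        assert len(db.sa_groups) == 1
        assert len(db.sa_groups[0].members) == 2

    def test_no_multi_taxa_entries_means_no_groups(self):
        db = make_sa_groups(db_from({"AAAA": {"Fusarium solani"}}))
        assert db.sa_groups == []


class TestMerge:
    def test_new_sa_from_conflicting_sources(self):
        a = make_sa_groups(db_from({"AAAA": {"Fusarium oxysporum"}}))
        b = make_sa_groups(db_from({"AAAA": {"Fusarium solani"}}))
        m = merge(a, b)
        assert m.entries["AAAA"].assigned_name == "Fusarium_SA1"
        assert m.entries["AAAA"].taxa == {"Fusarium oxysporum", "Fusarium solani"}

    def test_duplicate_elimination(self):
        a = make_sa_groups(db_from({"AAAA": {"Fusarium oxysporum"}}))
        b = make_sa_groups(db_from({"AAAA": {"Fusarium oxysporum"}}))
        m = merge(a, b)
        assert len(m.entries) == 1
        assert m.sa_groups == []

    def test_idempotent(self, ef1a_primers, small_fixture):
        _, fx = small_fixture
        db = make_sa_groups(filter_taxa(
            build_database(fx.records, genus="Fusarium", primers=ef1a_primers)))
        m = merge(db, db)
        assert m.to_dict()["entries"] == db.to_dict()["entries"]
        assert m.to_dict()["sa_groups"] == db.to_dict()["sa_groups"]

    def test_commutative_byte_identically(self):
        a = make_sa_groups(db_from({"AAAA": {"Fusarium x1"}, "CCCC": {"Fusarium x2"}}))
        b = make_sa_groups(db_from({"AAAA": {"Fusarium y1"}, "GGGG": {"Fusarium y2"}}))
        ab, ba = merge(a, b), merge(b, a)
        strip = lambda d: {k: v for k, v in d.to_dict().items()
                           if k not in ("provenance", "filter_log")}
        assert json.dumps(strip(ab), sort_keys=True) == json.dumps(strip(ba), sort_keys=True)

    def test_genus_mismatch_fatal(self):
        a = db_from({"AAAA": {"Fusarium x"}}, genus="Fusarium")
        b = db_from({"AAAA": {"Pythium y"}}, genus="Pythium")
        with pytest.raises(ValueError, match="Fusarium.*Pythium"):
            merge(a, b)


class TestSummarize:
    def test_hand_counted_example(self):
        db = make_sa_groups(db_from({
            "AAAA": {"Fusarium a", "Fusarium b"},
            "CCCC": {"Fusarium c"},
            "GGGG": {"Fusarium x complex"},
        }))
        s = summarize(db)
        assert s == {"total_variants": 3, "sa_variants": 1,
                     "species_complex_variants": 1, "species_taxa": 2,
                     "sa_taxa": 1, "attributions": 3}

    def test_empty_db_all_zero(self):
        s = summarize(AsvDatabase(genus="Fusarium"))
        assert set(s.values()) == {0}

    def test_fixture_ground_truth(self, ef1a_primers):
        spec = FixtureSpec(genus="Fusarium", n_species=4, n_records_per_species=1,
                           n_shared_amplicons=2, seed=11)
        fx = generate(spec, ef1a_primers)
        db = make_sa_groups(filter_taxa(
            build_database(fx.records, genus="Fusarium", primers=ef1a_primers)))
        assert summarize(db)["sa_variants"] == 2


class TestPersistence:
    def test_json_round_trip(self, ef1a_primers, small_fixture, tmp_path):
        _, fx = small_fixture
        db = make_sa_groups(filter_taxa(
            build_database(fx.records, genus="Fusarium", primers=ef1a_primers)))
        db.save(tmp_path / "db.json")
        back = AsvDatabase.load(tmp_path / "db.json")
        assert back.to_dict() == db.to_dict()

    def test_entry_sequences_unique_after_every_stage(self, ef1a_primers, small_fixture):
        _, fx = small_fixture
        db = build_database(fx.records, genus="Fusarium", primers=ef1a_primers)
        for stage in (db, filter_taxa(db), make_sa_groups(filter_taxa(db))):
            seqs = [e.sequence for e in stage.entries.values()]
            assert len(seqs) == len(set(seqs))
            assert all(s == k for k, s in
                       zip(stage.entries, (e.sequence for e in stage.entries.values())))
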