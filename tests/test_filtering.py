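import pytest

import ligandkit as lk


class TestFdrFilter:
    @pytest.fixture
    def mixed(self, make_peptide_set):
        seqs = [f"ACDEFGHI{a}" for a in "KLMNPQRST"] + ["WWWWWWWW"]
        ps = make_peptide_set(seqs)
        for r in ps.records[7:]:
            r.fdr_tier = "q05"
        return ps

    def test_strict_tier_drops_relaxed_records(self, mixed):
        assert len(lk.filter_fdr(mixed, "q01").records) == 7

    def test_relaxed_tier_keeps_all_with_flags(self, mixed):
        out = lk.filter_fdr(mixed, "q05")
        assert len(out.records) == 10
        assert sum(r.fdr_tier == "q05" for r in out.records) == 3

    def test_empty_set(self, make_peptide_set):
        assert lk.filter_fdr(make_peptide_set([]), "q01").records == []

    def test_unknown_tier_rejected(self, mixed):
        with pytest.raises(ValueError):
            lk.filter_fdr(mixed, "q10")


class TestLengthFilter:
    def test_window_inclusive(self, make_peptide_set):
        ps = make_peptide_set(["A" * 7, "C" * 8, "D" * 14, "E" * 15])
        kept = lk.filter_length(ps)
        assert sorted(r.length for r in kept.records) == [8, 14]

    def test_degenerate_window_selects_single_length(self, make_peptide_set):
        ps = make_peptide_set(["A" * 8, "C" * 9, "D" * 10])
        kept = lk.filter_length(ps, 9, 9)
        assert [r.length for r in kept.records] == [9]

    def test_inverted_window_is_error(self, make_peptide_set):
        with pytest.raises(ValueError):
            lk.filter_length(make_peptide_set([]), 10, 8)


class TestContaminantCull:
    def test_counts_and_flags(self, make_peptide_set):
        ps = make_peptide_set(["A" * 8, "C" * 8, "D" * 8, "E" * 8, "F" * 8])
        ps.records[0].source_accession = "KRT1"
        ps.records[1].source_accession = "ALB"
        kept, rep = lk.cull_contaminants(ps, {"KRT1", "ALB"})
        assert (rep.kept_count, rep.culled_crapome) == (3, 2)
        # culled records are retained, flagged, and excluded from the unique view
        assert len(kept.records) == 5
        assert len(kept.unique_sequences) == 3

    def test_empty_list_is_identity(self, make_peptide_set):
        ps = make_peptide_set(["A" * 8])
        kept, rep = lk.cull_contaminants(ps, set())
        assert rep.culled_crapome == 0 and kept.unique_sequences == ps.unique_sequences


class TestFindNests:
    def brute_force_nests(self, seqs):
        maximal = [s for s in seqs if not any(s != t and s in t for t in seqs)]
        return {m: sorted(t for t in seqs if t != m and t in m) for m in maximal}

    def test_single_nest_two_members(self, make_peptide_set):
        ps = make_peptide_set(["KLMNPQRST", "LMNPQRST", "MNPQR"], rt=[1.0, 2.0, 3.0])
        groups = lk.find_nests(ps)
        assert len(groups) == 1
        g = groups[0]
        assert g.parent.sequence == "KLMNPQRST"
        assert [m.sequence for m in g.members] == ["LMNPQRST", "MNPQR"]

    def test_disjoint_sequences_give_memberless_groups(self, make_peptide_set):
        ps = make_peptide_set(["ACDEFGHI", "STVWYRQN"], rt=[1.0, 2.0])
        groups = lk.find_nests(ps)
        assert len(groups) == 2 and all(not g.members for g in groups)

    def test_shared_substring_appears_in_both_groups(self, make_peptide_set):
        ps = make_peptide_set(["ACDEFG", "CDE", "WYCDEHK"], rt=[1.0, 2.0, 3.0])
        groups = lk.find_nests(ps)
        parents = {g.parent.sequence: [m.sequence for m in g.members] for g in groups}
        assert parents == self.brute_force_nests(["ACDEFG", "CDE", "WYCDEHK"])
        assert parents["ACDEFG"] == ["CDE"] and parents["WYCDEHK"] == ["CDE"]


class TestCullNested:
    def make(self, make_peptide_set, rts):
        return make_peptide_set(["KLMNPQRST", "LMNPQRST"], rt=rts)

    def test_co_eluting_member_culled(self, make_peptide_set):
        kept, rep = lk.cull_nested(self.make(make_peptide_set, [1000.0, 1010.0]))
        assert rep.culled_nested == 1
        assert kept.unique_sequences == {"KLMNPQRST"}
        assert rep.witnesses == [("LMNPQRST", "KLMNPQRST", pytest.approx(10.0))]

    def test_member_outside_window_kept(self, make_peptide_set):
        kept, rep = lk.cull_nested(self.make(make_peptide_set, [1000.0, 1040.0]))
        assert rep.culled_nested == 0
        assert len(kept.unique_sequences) == 2

    def test_window_boundary_is_inclusive(self, make_peptide_set):
        _, rep = lk.cull_nested(self.make(make_peptide_set, [1000.0, 1030.0]))
        assert rep.culled_nested == 1

    def test_missing_rt_never_culled_but_counted(self, make_peptide_set):
        ps = make_peptide_set(["KLMNPQRST", "LMNPQRST"], rt=[1000.0, None])
        kept, rep = lk.cull_nested(ps)
        assert rep.culled_nested == 0 and rep.unevaluated_no_rt == 1

    def test_different_runs_never_witness(self, make_peptide_set):
        a = make_peptide_set(["KLMNPQRST"], run_id="run1", rt=[1000.0])
        b = make_peptide_set(["LMNPQRST"], run_id="run2", rt=[1005.0])
        ps = lk.PeptideSet(records=a.records + b.records)
        _, rep = lk.cull_nested(ps)
        assert rep.culled_nested == 0

    def test_single_pass_culls_full_chain(self, make_peptide_set):
        # A < B < C all co-elute: both A and B culled against the original set
        ps = make_peptide_set(
            ["CDEFG", "ACDEFGH", "KACDEFGHI"], rt=[1000.0, 1010.0, 1020.0]
        )
        kept, rep = lk.cull_nested(ps)
        assert rep.culled_nested == 2
        assert kept.unique_sequences == {"KACDEFGHI"}

    def test_idempotent(self, make_peptide_set):
        ps = make_peptide_set(
            ["CDEFG", "ACDEFGH", "KACDEFGHI"], rt=[1000.0, 1010.0, 1020.0]
        )
        once, _ = lk.cull_nested(ps)
        twice, rep2 = lk.cull_nested(once)
        assert rep2.culled_nested == 0
        assert {r.sequence for r in twice.records} == {r.sequence for r in once.records}

    def test_witness_is_longest_parent(self, make_peptide_set):
        ps = make_peptide_set(
            ["CDE", "ACDEFG", "WCDEFGHIK"], rt=[1000.0, 1001.0, 1002.0]
        )
        _, rep = lk.cull_nested(ps)
        by_seq = {w[0]: w[1] for w in rep.witnesses}
        assert by_seq["CDE"] == "WCDEFGHIK"

    def test_negative_window_is_error(self, make_peptide_set):
        with pytest.raises(ValueError):
            lk.cull_nested(make_peptide_set([]), -1.0)

    def test_output_subset_with_witness_per_culled(self, make_peptide_set):
        ps = make_peptide_set(
            ["KLMNPQRST", "LMNPQRST", "MNPQRS", "ACDEFGHW"],
            rt=[1000.0, 1010.0, 2000.0, 1005.0],
        )
        kept, rep = lk.cull_nested(ps)
        culled = {r.sequence for r in kept.records if r.culled == "nested"}
        assert culled == {w[0] for w in rep.witnesses}
        assert all(w[2] <= 30.0 for w in rep.witnesses)


class TestPlantedArtifacts:
    def test_removes_all_planted_within_window_and_nothing_else(self, a3_ligandome_2000):
        base, _ = a3_ligandome_2000
        withart, truth = lk.inject_truncations(base, rate=0.15, jitter_s=20, seed=5)
        kept, rep = lk.cull_nested(withart, 30)
        culled = {r.sequence for r in kept.records if r.culled == "nested"}
        assert culled == set(truth.labels)  # all artifacts, only artifacts

    def test_removes_none_outside_window(self, a3_ligandome_2000):
        base, _ = a3_ligandome_2000
        withart, truth = lk.inject_truncations(base, rate=0.15, jitter_s=120, seed=5)
        # jitter magnitudes lie in [60, 120] s, all beyond the 30 s window
        kept, rep = lk.cull_nested(withart, 30)
        assert rep.culled_nested == 0


class TestFilterCascade:
    def test_counts_conserved_and_order_fixed(self, make_peptide_set):
        ps = make_peptide_set(
            ["A" * 7, "KLMNPQRST", "LMNPQRST", "CDEFGHIK", "WYWYWYWYW"],
            rt=[None, 1000.0, 1010.0, 500.0, 600.0],
        )
        ps.records[3].source_accession = "KRT1"
        ps.records[4].fdr_tier = "q05"
        kept, rep = lk.apply_filters(
            ps, fdr_tier="q01", contaminant_accessions={"KRT1"}
        )
        assert rep.input_count == 5
        assert rep.culled_fdr == 1       # WYWYWYWYW
        assert rep.culled_length == 1    # 7-mer
        assert rep.culled_crapome == 1   # CDEFGHIK
        assert rep.culled_nested == 1    # LMNPQRST
        assert rep.kept_count == 1
        assert kept.unique_sequences == {"KLMNPQRST"}
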