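import pytest
from hypothesis import given, strategies as st

import ligandkit as lk
from ligandkit.mapping import (
    N_WITHIN_PEPTIDE,
    SEQUON_SPANS_BOUNDARY,
    sequon_peptide_intersection,
)

protein_seqs = st.text(alphabet=lk.AMINO_ACIDS, min_size=6, max_size=60)


def make_protein(seq, accession="P1", features=()):
    return lk.ProteinRecord(accession=accession, sequence=seq, features=list(features))


class TestPlacePeptides:
    def test_single_occurrence_coordinates(self):
        placements, unplaced = lk.place_peptides(["CDEF"], make_protein("ACDEFGHIKL"))
        assert unplaced == []
        p = placements[0]
        assert (p.start, p.end) == (2, 5)
        assert "ACDEFGHIKL"[p.start0 : p.end0] == "CDEF"

    def test_overlapping_occurrences_all_reported(self):
        placements, _ = lk.place_peptides(["AA"], make_protein("AAAA"))
        assert [p.start for p in placements] == [1, 2, 3]
        assert all(p.occurrences == 3 for p in placements)

    def test_unplaced_reported_separately(self):
        placements, unplaced = lk.place_peptides(
            ["CDEF", "WWWW"], make_protein("ACDEFGHIKL")
        )
        assert unplaced == ["WWWW"]

    def test_placement_invariant_subsequence_equality(self, msln_protein, msln_peptides):
        placements, unplaced = lk.place_peptides(msln_peptides, msln_protein)
        assert unplaced == []
        for p in placements:
            assert msln_protein.sequence[p.start - 1 : p.end] == p.peptide
            assert p.end - p.start + 1 == len(p.peptide)

    @given(protein_seqs, st.integers(2, 5))
    def test_matches_brute_force_all_substrings_oracle(self, seq, k):
        protein = make_protein(seq)
        peptides = sorted({seq[i : i + k] for i in range(len(seq) - k + 1)})
        placements, unplaced = lk.place_peptides(peptides, protein)
        assert unplaced == []
        got = {(p.peptide, p.start) for p in placements}
        expected = {
            (pep, i + 1)
            for pep in peptides
            for i in range(len(seq) - k + 1)
            if seq[i : i + k] == pep
        }
        assert got == expected


class TestCoverage:
    def test_simple_fraction(self):
        protein = make_protein("ACDEFGHIKL")
        placements, _ = lk.place_peptides(["CDEF"], protein)
        assert lk.coverage(placements, protein).coverage_fraction == pytest.approx(0.4)

    def test_union_of_overlapping_placements(self):
        protein = make_protein("ACDEFGHIKL")
        placements, _ = lk.place_peptides(["ACDEF", "EFGHI"], protein)  # [1..5], [4..8]
        cov = lk.coverage(placements, protein)
        assert cov.coverage_fraction == pytest.approx(0.8)
        assert cov.covered_positions == set(range(1, 9))

    def test_no_placements_zero(self):
        cov = lk.coverage([], make_protein("ACDEFGHIKL"))
        assert cov.coverage_fraction == 0.0

    def test_monotone_under_added_placements(self):
        protein = make_protein("ACDEFGHIKLMNPQRSTVWY")
        p1, _ = lk.place_peptides(["ACDEF"], protein)
        p2, _ = lk.place_peptides(["ACDEF", "STVWY"], protein)
        assert (
            lk.coverage(p2, protein).coverage_fraction
            >= lk.coverage(p1, protein).coverage_fraction
        )

    def test_per_region_fractions(self):
        protein = make_protein(
            "ACDEFGHIKL", features=[("domain_boundary", 1, 5, "N"), ("domain_boundary", 6, 10, "C")]
        )
        placements, _ = lk.place_peptides(["ACDEF"], protein)
        cov = lk.coverage(placements, protein)
        assert cov.per_region_coverage == {"N": 1.0, "C": 0.0}

    def test_wrong_protein_rejected(self):
        placements, _ = lk.place_peptides(["CDEF"], make_protein("ACDEFGHIKL", "P1"))
        with pytest.raises(ValueError):
            lk.coverage(placements, make_protein("ACDEFGHIKL", "P2"))


class TestFindSequons:
    def test_proline_blocked_site_excluded(self):
        # the first N is followed by P (no site); the second N starts NIS
        sites = lk.find_sequons(make_protein("GVLANPPNIS"))
        assert [(s.position, s.triplet) for s in sites] == [(8, "NIS")]

    def test_npt_excluded_by_proline_rule(self):
        assert lk.find_sequons(make_protein("ANPTA")) == []
        assert [s.triplet for s in lk.find_sequons(make_protein("ANPTA"), exclude_proline=False)] == ["NPT"]

    def test_overlapping_windows_both_found(self):
        sites = lk.find_sequons(make_protein("ANNSSA"))
        assert [(s.position, s.triplet) for s in sites] == [(2, "NNS"), (3, "NSS")]

    @given(protein_seqs, st.booleans())
    def test_matches_regex_oracle(self, seq, exclude_proline):
        # independent oracle: explicit window scan
        expected = []
        for i in range(len(seq) - 2):
            n, x, st_ = seq[i], seq[i + 1], seq[i + 2]
            if n == "N" and st_ in "ST" and (x != "P" or not exclude_proline):
                expected.append(i + 1)
        got = [s.position for s in lk.find_sequons(make_protein(seq), exclude_proline)]
        assert got == expected


class TestSequonPeptideIntersection:
    def test_boundary_spanning_sequon(self):
        # peptide ends on the sequon N; S/T completes past the C-terminus
        protein = make_protein("AGVLANPPNISA")
        placements, _ = lk.place_peptides(["GVLANPPNI"], protein)
        sequons = lk.find_sequons(protein)
        rels = sequon_peptide_intersection(placements, sequons)
        assert len(rels) == 1
        _, sq, rel = rels[0]
        assert sq.triplet == "NIS" and rel == SEQUON_SPANS_BOUNDARY

    def test_fully_contained_sequon(self):
        protein = make_protein("AANVTAAAA")
        placements, _ = lk.place_peptides(["ANVTA"], protein)
        rels = sequon_peptide_intersection(placements, lk.find_sequons(protein))
        assert [r for _, _, r in rels] == [N_WITHIN_PEPTIDE]

    def test_peptide_without_asparagine_empty(self):
        protein = make_protein("AANVTAAAA")
        placements, _ = lk.place_peptides(["AAAA"], protein)
        assert sequon_peptide_intersection(placements, lk.find_sequons(protein)) == []


class TestModificationReport:
    def make_phospho_set(self):
        # 27 observations of one peptide: 2 phospho-S (P3), 25 phospho-T (P4)
        records = []
        for i in range(27):
            if i < 2:
                mods = (lk.Modification(3, "phospho", 0.9, 79.966),)
            else:
                mods = (lk.Modification(4, "phospho", 0.95, 79.966),)
            records.append(
                lk.PeptideRecord(sequence="FTSTPPKPK", modifications=mods, run_id=f"r{i}")
            )
        return lk.PeptideSet(name="phos", records=records)

    def test_published_phospho_fractions(self):
        protein = make_protein("AAFTSTPPKPKAA")
        pset = self.make_phospho_set()
        placements, _ = lk.place_peptides(pset, protein)
        df = lk.modification_report(pset, placements)
        by_residue = {r.residue: r for r in df.itertuples(index=False)}
        assert by_residue["S"].fraction * 100 == pytest.approx(7.4, abs=0.05)
        assert by_residue["T"].fraction * 100 == pytest.approx(92.6, abs=0.05)
        assert by_residue["S"].position == 5  # S of FTSTP at protein position 5
        assert by_residue["T"].position == 6

    def test_no_modifications_empty_report(self, make_peptide_set):
        protein = make_protein("AAFTSTPPKPKAA")
        pset = make_peptide_set(["FTSTPPKPK"])
        placements, _ = lk.place_peptides(pset, protein)
        assert lk.modification_report(pset, placements).empty

    def test_multi_occurrence_peptide_reported_at_both_loci(self):
        protein = make_protein("CDEFGWWCDEFGW")
        rec = lk.PeptideRecord(sequence="CDEFG", modifications=(lk.Modification(2, "ox"),))
        pset = lk.PeptideSet(records=[rec])
        placements, _ = lk.place_peptides(pset, protein)
        df = lk.modification_report(pset, placements)
        assert sorted(df.position) == [2, 9]  # D at both occurrences
        assert set(df.residue) == {"D"}


class TestMslnReference:
    def test_four_sequons_one_in_mpf(self, msln_protein):
        sites = lk.find_sequons(msln_protein)
        assert len(sites) == 4
        furin_end = 295
        mpf = [s for s in sites if s.position <= furin_end]
        assert len(mpf) == 1 and mpf[0].triplet == "NIS"

    def test_target_peptide_coverage_over_half(self, msln_protein, msln_peptides):
        placements, unplaced = lk.place_peptides(msln_peptides, msln_protein)
        cov = lk.coverage(placements, msln_protein)
        assert unplaced == []
        assert cov.coverage_fraction > 0.5
        # coverage is comparable over the two proprotein moieties
        assert abs(cov.per_region_coverage["MPF"] - cov.per_region_coverage["MSLN"]) < 0.15
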