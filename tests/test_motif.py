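import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import ligandkit as lk
from ligandkit.motif import AA_INDEX, N_AA


def kl_oracle(p, q):
    """Independent brute-force KL divergence in bits (0*log0 := 0)."""
    total = 0.0
    for pi, qi in zip(p, q):
        if pi > 0:
            total += pi * math.log2(pi / qi)
    return total


class TestBackground:
    def test_bundled_uniprot_table_normalized_and_positive(self):
        bg = lk.BackgroundFrequencies.uniprot()
        arr = bg.as_array()
        assert arr.sum() == pytest.approx(1.0, abs=1e-9)
        assert arr.min() > 0
        # leucine is the most common residue in the proteome background
        assert bg.freq["L"] == max(bg.freq.values())

    def test_missing_letter_rejected(self):
        with pytest.raises(ValueError):
            lk.BackgroundFrequencies({a: 0.05 for a in "ACDEFGHIKLMNPQRSTVW"})


class TestBuildPfm:
    def test_single_peptide_point_mass(self):
        pfm = lk.build_pfm(["AAAAAAAAA"], 9)
        assert pfm.n_peptides == 1
        assert all(pfm.freqs[i][AA_INDEX["A"]] == 1.0 for i in range(9))

    def test_two_peptides_split_final_position(self):
        pfm = lk.build_pfm(["ACDEFGHIK", "ACDEFGHIR"], 9)
        assert pfm.freqs[8][AA_INDEX["K"]] == pytest.approx(0.5)
        assert pfm.freqs[8][AA_INDEX["R"]] == pytest.approx(0.5)

    def test_planted_anchor_is_argmax(self, a3_ligandome_2000):
        pset, truth = a3_ligandome_2000
        pfm = lk.build_pfm(pset, 9)
        p9 = pfm.freqs[8]
        assert lk.AMINO_ACIDS[int(np.argmax(p9))] in truth.anchor_positions[9][9]

    def test_pseudocount_policy(self):
        pfm = lk.build_pfm(["AAAAAAAAA"], 9, pseudocount=1.0)
        assert pfm.freqs[0][AA_INDEX["A"]] == pytest.approx(2.0 / 21.0)
        assert pfm.freqs[0][AA_INDEX["C"]] == pytest.approx(1.0 / 21.0)
        assert pfm.freqs.sum(axis=1) == pytest.approx(np.ones(9))

    def test_no_matching_length_is_error(self):
        with pytest.raises(ValueError):
            lk.build_pfm(["ACDEFGHIK"], 10)


class TestLogoHeights:
    def test_zero_when_observed_equals_background(self):
        # 20 peptides hitting each letter once per position = uniform pfm
        seqs = [a * 9 for a in lk.AMINO_ACIDS]
        pfm = lk.build_pfm(seqs, 9)
        logo = lk.logo_heights(pfm, lk.BackgroundFrequencies.uniform())
        assert np.allclose(logo.heights, 0.0, atol=1e-12)
        assert np.allclose(logo.per_position_total, 0.0, atol=1e-12)

    def test_point_mass_vs_uniform_is_log2_20(self):
        logo = lk.logo_heights(
            lk.build_pfm(["AAAAAAAAA"], 9), lk.BackgroundFrequencies.uniform()
        )
        assert logo.per_position_total == pytest.approx(math.log2(20), abs=1e-12)

    @given(st.integers(0, 2**32 - 1))
    def test_totals_match_independent_kl_oracle(self, seed):
        rng = np.random.default_rng(seed)
        counts = rng.multinomial(50, np.ones(N_AA) / N_AA, size=4)
        pfm = lk.PositionFrequencyMatrix(length=4, counts=counts, n_peptides=50)
        bg = lk.BackgroundFrequencies.uniprot()
        logo = lk.logo_heights(pfm, bg)
        q = bg.as_array()
        for i in range(4):
            assert logo.per_position_total[i] == pytest.approx(
                kl_oracle(pfm.freqs[i], q), abs=1e-9
            )
            assert logo.per_position_total[i] >= 0

    def test_height_signs_follow_enrichment(self):
        pfm = lk.build_pfm(["AAAAAAAAA"], 9)
        logo = lk.logo_heights(pfm, lk.BackgroundFrequencies.uniprot())
        a = AA_INDEX["A"]
        assert logo.heights[0][a] > 0
        # absent letters contribute 0 at pseudocount 0 (0*log0 limit)
        assert logo.heights[0][AA_INDEX["W"]] == 0.0

    def test_rank_orders_by_absolute_height(self, a3_ligandome_2000):
        pset, _ = a3_ligandome_2000
        logo = lk.logo_heights(lk.build_pfm(pset, 9), lk.BackgroundFrequencies.uniprot())
        for i in range(9):
            hs = [abs(logo.heights[i][AA_INDEX[a]]) for a in logo.rank_by_height[i]]
            assert all(x >= y for x, y in zip(hs, hs[1:]))

    def test_p1_shifted_8mers_show_p1_anchor_signal(self):
        import dataclasses

        spec = dataclasses.replace(
            lk.presets()["A*24:02"],
            length_weights={8: 1.0},
            p1_shift_fraction=0.4,
        )
        pset, truth = lk.sample_ligandome(spec, lk.SimulationConfig(n_peptides=1500, seed=21))
        pfm = lk.build_pfm(pset, 8)
        bg = lk.BackgroundFrequencies.uniprot()
        logo = lk.logo_heights(pfm, bg)
        anchor_letter = "Y"  # planted P2 preference echoed at P1
        y = AA_INDEX[anchor_letter]
        baseline = np.mean([logo.heights[i][y] for i in (3, 4, 5)])
        assert logo.heights[0][y] > baseline + 0.05


class TestLengthDistribution:
    def test_uniform_length_mean(self, make_peptide_set):
        ps = make_peptide_set([a * 9 for a in "ACDEFGHIKL"])
        counts, mean = lk.length_distribution(ps)
        assert counts == {9: 10} and mean == 9.0

    def test_symmetric_mixture_mean(self, make_peptide_set):
        ps = make_peptide_set([a * 8 for a in "ACDEF"] + [a * 10 for a in "GHIKL"])
        _, mean = lk.length_distribution(ps)
        assert mean == 9.0

    def test_empty_set_is_error(self, make_peptide_set):
        with pytest.raises(ValueError):
            lk.length_distribution(make_peptide_set([]))

    def test_allele_length_skew_recovered(self):
        p = lk.presets()
        a11, _ = lk.sample_ligandome(p["A*11:01"], lk.SimulationConfig(2000, seed=31))
        a2, _ = lk.sample_ligandome(p["A*02:01"], lk.SimulationConfig(2000, seed=32))
        _, mean11 = lk.length_distribution(a11)
        _, mean2 = lk.length_distribution(a2)
        assert mean11 > mean2  # A*11:01 preset skews longer


class TestBinderClassSummary:
    def test_multi_allele_sum_exceeds_100(self, make_peptide_set):
        ps = make_peptide_set(["ACDEFGHIK"])
        anns = [
            lk.BinderAnnotation("ACDEFGHIK", "A*02:01", "strong"),
            lk.BinderAnnotation("ACDEFGHIK", "A*03:01", "strong"),
            lk.BinderAnnotation("ACDEFGHIK", "A*11:01", "non"),
        ]
        df = lk.binder_class_summary(ps, anns, ["A*02:01", "A*03:01", "A*11:01"])
        assert df.loc[9, "strong"] == pytest.approx(200.0)
        assert df.loc[9, "non"] == pytest.approx(100.0)

    def test_all_non_binders_sum_to_100_per_allele(self, make_peptide_set):
        seqs = ["ACDEFGHIK", "CDEFGHIKL"]
        ps = make_peptide_set(seqs)
        alleles = ["A*02:01", "A*03:01", "A*11:01"]
        anns = [lk.BinderAnnotation(s, al, "non") for s in seqs for al in alleles]
        df = lk.binder_class_summary(ps, anns, alleles)
        assert df.loc[9, "non"] == pytest.approx(300.0)
        assert df.loc[9, "strong"] == 0.0

    def test_known_fractions_recovered(self, make_peptide_set):
        seqs = [f"ACDEFGHI{a}" for a in "KLMNP"]
        ps = make_peptide_set(seqs)
        anns = [
            lk.BinderAnnotation(s, "A*02:01", "strong" if i < 2 else "weak")
            for i, s in enumerate(seqs)
        ]
        df = lk.binder_class_summary(ps, anns, ["A*02:01"])
        assert df.loc[9, "strong"] == pytest.approx(40.0)
        assert df.loc[9, "weak"] == pytest.approx(60.0)

    def test_missing_annotation_lists_pairs(self, make_peptide_set):
        ps = make_peptide_set(["ACDEFGHIK"])
        with pytest.raises(ValueError, match="ACDEFGHIK/A\\*02:01"):
            lk.binder_class_summary(ps, [], ["A*02:01"])


class TestCompartmentProfile:
    def test_single_source_all_cytosol(self, make_peptide_set):
        ps = make_peptide_set(["ACDEFGHIK", "CDEFGHIKL"])
        for r in ps.records:
            r.source_accession = "P1"
        prof = lk.compartment_profile(ps, {"P1": "Cytosol"})
        assert prof["Cytosol"] == 100.0 and prof["unmapped"] == 0.0

    def test_absent_mapping_all_unmapped(self, make_peptide_set):
        ps = make_peptide_set(["ACDEFGHIK"])
        assert lk.compartment_profile(ps, {})["unmapped"] == 100.0

    def test_constructed_extracellular_fraction(self, make_peptide_set):
        seqs = [f"ACDEFGH{a}{b}" for a in "IKLMNPQRST" for b in "IKLMNPQRST"]
        ps = make_peptide_set(seqs)
        mapping = {}
        for i, r in enumerate(ps.records):
            r.source_accession = f"P{i}"
            mapping[f"P{i}"] = "Extracellular" if i < 7 else "Cytosol"
        prof = lk.compartment_profile(ps, mapping)
        assert prof["Extracellular"] == pytest.approx(7.0)
        assert sum(prof.values()) == pytest.approx(100.0)
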