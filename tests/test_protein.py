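"""Translation, mass, FU annotation, insertion calls, hydropathy, cysteines."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hemasm as hm
from hemasm.protein import AVERAGE_RESIDUE_MASS, WATER_DA

PROTEIN_ALPHABET = "".join(sorted(AVERAGE_RESIDUE_MASS))
peptides = st.text(alphabet=PROTEIN_ALPHABET, min_size=1, max_size=40)


class TestFindOrfTranslate:
    def test_minimal_orf(self):
        record = hm.find_orf_translate("ATGGGTTAA", min_orf_nt=9)
        assert record.seq == "MG"
        assert len(record) == 2

    def test_protein_length_is_cds_over_three_minus_one(self, truth_one_species):
        for label, cds in truth_one_species.genes.items():
            record = hm.find_orf_translate(truth_one_species.transcripts[label])
            assert len(record) == len(cds) // 3 - 1
            assert record.seq == truth_one_species.proteins[label]

    def test_reverse_strand_orf_found(self, truth_one_species):
        from hemasm._seq import revcomp

        record = hm.find_orf_translate(revcomp(truth_one_species.transcripts["H1_sp1"]))
        assert record.seq == truth_one_species.proteins["H1_sp1"]

    def test_no_atg_is_an_error(self):
        with pytest.raises(ValueError):
            hm.find_orf_translate("CCCCCCCCCTAACCC", min_orf_nt=9)

    def test_internal_n_translated_as_x_and_flagged(self):
        record = hm.find_orf_translate("ATGGGTANTGGGTAA", min_orf_nt=15)
        assert "X" in record.seq
        assert record.has_ambiguous


class TestMolecularWeight:
    def test_glycine(self):
        assert hm.molecular_weight("G") == pytest.approx(75.07, abs=0.01)

    def test_diglycine_additivity(self):
        assert hm.molecular_weight("GG") == pytest.approx(132.12, abs=0.01)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            hm.molecular_weight("")

    def test_nonstandard_residue_rejected_with_positions(self):
        with pytest.raises(ValueError, match=r"\[2\]"):
            hm.molecular_weight("GXG")

    def test_agrees_with_biopython(self):
        from Bio.SeqUtils import molecular_weight as bp_mw

        seq = "MKWVTFISLLFLFSSAYS"
        assert hm.molecular_weight(seq) == pytest.approx(
            bp_mw(seq, seq_type="protein"), abs=0.5
        )

    @settings(derandomize=True, max_examples=50)
    @given(a=peptides, b=peptides)
    def test_mass_additivity(self, a, b):
        lhs = hm.molecular_weight(a + b)
        rhs = hm.molecular_weight(a) + hm.molecular_weight(b) - WATER_DA
        assert lhs == pytest.approx(rhs, abs=1e-6)

    @settings(derandomize=True, max_examples=50)
    @given(seq=peptides)
    def test_composition_sums_to_one(self, seq):
        assert sum(hm.composition(seq).values()) == pytest.approx(1.0, abs=1e-9)


class TestAnnotateFus:
    def test_identity_projection(self, truth_one_species):
        ref = truth_one_species.proteins["H1_sp1"]
        annotation = hm.annotate_fus(ref, ref, truth_one_species.fu_boundaries)
        expected = [(n, s + 1, e) for n, s, e in truth_one_species.fu_boundaries]
        assert annotation.segments == expected

    def test_insert_extends_host_fu(self, truth_one_species):
        ann = hm.annotate_fus(
            truth_one_species.proteins["H2_sp1"],
            truth_one_species.proteins["H1_sp1"],
            truth_one_species.fu_boundaries,
        )
        host = truth_one_species.spec.h2_insert.host_fu
        ins_len = truth_one_species.spec.h2_insert.length_aa
        ref_len = dict(
            (n, e - s) for n, s, e in truth_one_species.fu_boundaries
        )[host]
        start, end = ann.segment(host)
        assert (end - start + 1) == pytest.approx(ref_len + ins_len, abs=2)

    def test_truncated_protein_annotates_only_present_fus(self, truth_one_species):
        bounds = truth_one_species.fu_boundaries
        # drop the terminal domain (collar loss, as in wall-only decamers)
        truncated = truth_one_species.proteins["H1_sp1"][: bounds[-2][2]]
        ann = hm.annotate_fus(
            truncated, truth_one_species.proteins["H1_sp1"], bounds
        )
        names = [n for n, _s, _e in ann.segments]
        assert names == [n for n, _s, _e in bounds[:-1]]

    def test_unrelated_sequence_rejected(self, truth_one_species):
        with pytest.raises(ValueError):
            hm.annotate_fus(
                "MKLV" * 30,
                truth_one_species.proteins["H1_sp1"],
                truth_one_species.fu_boundaries,
            )


class TestCallInsertion:
    def test_identical_sequences_give_no_calls(self, truth_one_species):
        p = truth_one_species.proteins["H1_sp1"]
        assert hm.call_insertion(p, p) == []

    def test_recovers_configured_340_aa_insert_at_full_scale(self):
        truth = hm.generate_paralog_pair(hm.ParalogPairSpec(seed=1, species_divergence=0.0))
        calls = hm.call_insertion(
            truth.proteins["H2_sp1"],
            truth.proteins["H1_sp1"],
            counterpart_fus=truth.fu_boundaries,
        )
        assert len(calls) == 1
        call = calls[0]
        assert call.length_aa == pytest.approx(340, abs=2)
        assert call.his_asp_fraction >= 0.68
        assert call.host_fu == "g"
        assert call.mean_hydropathy < 0

    def test_self_comparison_empty_for_all_paralogs(self, scaled_truth):
        for protein in scaled_truth.proteins.values():
            assert hm.call_insertion(protein, protein) == []


class TestHydropathy:
    def test_poly_ile_is_constant_max(self):
        profile = hm.hydropathy_profile("I" * 30)
        assert np.allclose(profile.values, 4.5)

    def test_poly_arg_is_constant_min(self):
        profile = hm.hydropathy_profile("R" * 30)
        assert np.allclose(profile.values, -4.5)

    @settings(derandomize=True, max_examples=30)
    @given(seq=st.text(alphabet=PROTEIN_ALPHABET, min_size=9, max_size=60))
    def test_reversal_symmetry(self, seq):
        fwd = hm.hydropathy_profile(seq).values
        rev = hm.hydropathy_profile(seq[::-1]).values
        assert np.allclose(fwd, rev[::-1])

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            hm.hydropathy_profile("ACDEFGHIKL", window=8)

    def test_his_asp_rich_insert_is_hydrophilic(self, truth_one_species):
        s, e = truth_one_species.insert_coords["H2_sp1"]
        segment = truth_one_species.proteins["H2_sp1"][s:e]
        profile = hm.hydropathy_profile(segment)
        assert profile.values.mean() < 0


class TestCysteineCensus:
    def test_self_comparison_all_canonical(self, truth_one_species):
        p = truth_one_species.proteins["H1_sp1"]
        report = hm.cysteine_census(p, p)
        assert report.additional == []
        assert len(report.canonical) == p.count("C")

    def test_engineered_additional_cysteine_detected(self, truth_one_species):
        ref = truth_one_species.proteins["H1_sp1"]
        first_c = ref.index("C")
        site = 500
        while ref[site] == "C":
            site += 1
        query = list(ref)
        query[first_c] = "A"  # lose one canonical cysteine
        query[site] = "C"  # gain a novel one
        report = hm.cysteine_census("".join(query), ref)
        assert report.additional == [site + 1]
        assert (first_c + 1) not in report.canonical
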