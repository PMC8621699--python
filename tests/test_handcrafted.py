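import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lgfc.handcrafted_features import (
    RED_DIM,
    aac,
    assemble_handcrafted,
    dnc,
    fickett_score,
    find_longest_orf,
    nucleotide_ctd,
    protein_kmer,
    red_features,
    register_encoder,
    registered_encoders,
    rna_kmer,
)
from lgfc.sequence_encoding import reduce_alphabet

clean_rna = st.text(alphabet="ACGU", min_size=5, max_size=150)
clean_protein = st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=5, max_size=120)


def brute_force_kmer_counts(seq: str, alphabet: str, k: int) -> np.ndarray:
    """Independent sliding-window counter (oracle)."""
    kmers = ["".join(p) for p in itertools.product(alphabet, repeat=k)]
    return np.array([sum(1 for i in range(len(seq) - k + 1) if seq[i : i + k] == m)
                     for m in kmers], dtype=float)


class TestDNC:
    def test_acgu_has_thirds_at_ac_cg_gu(self):
        v = dnc("ACGU")
        idx = {m: i for i, m in enumerate("".join(p) for p in itertools.product("ACGU", repeat=2))}
        expected = np.zeros(16)
        for m in ("AC", "CG", "GU"):
            expected[idx[m]] = 1 / 3
        np.testing.assert_allclose(v, expected)

    def test_homopolymer(self):
        v = dnc("AAAA")
        assert v[0] == 1.0 and v[1:].sum() == 0

    def test_output_length_16(self):
        assert dnc("ACGUACGU").shape == (16,)

    def test_too_short_errors(self):
        with pytest.raises(ValueError):
            dnc("A")

    @given(seq=clean_rna)
    @settings(max_examples=50, deadline=None)
    def test_clean_sequences_sum_to_one(self, seq):
        assert dnc(seq).sum() == pytest.approx(1.0)

    def test_n_containing_dinucleotides_skipped(self):
        # "ANA": both dinucleotides contain N -> all zero, denominator N-1
        assert dnc("ANA").sum() == 0.0


class TestRnaKmer:
    def test_aaaa_3mer(self):
        v = rna_kmer("AAAA", 3)
        assert v[0] == pytest.approx(0.5)  # AAA twice / N=4
        assert v[1:].sum() == 0

    def test_length_64(self):
        assert rna_kmer("ACGUACGU", 3).shape == (64,)

    @given(seq=clean_rna)
    @settings(max_examples=50, deadline=None)
    def test_sum_identity(self, seq):
        n = len(seq)
        assert rna_kmer(seq, 3).sum() == pytest.approx((n - 3 + 1) / n)

    @given(seq=clean_rna, k=st.integers(1, 3))
    @settings(max_examples=60, deadline=None)
    def test_matches_brute_force_counter(self, seq, k):
        expected = brute_force_kmer_counts(seq, "ACGU", k) / len(seq)
        np.testing.assert_allclose(rna_kmer(seq, k), expected)

    def test_too_short_errors(self):
        with pytest.raises(ValueError):
            rna_kmer("AC", 3)


class TestAAC:
    def test_homopolymer_is_100(self):
        v = aac("AAAA")
        assert v[0] == 100.0 and v[1:].sum() == 0

    def test_fifty_fifty(self):
        v = aac("ACACAC")
        assert v[0] == pytest.approx(50.0) and v[1] == pytest.approx(50.0)

    @given(seq=clean_protein)
    @settings(max_examples=50, deadline=None)
    def test_sums_to_100_without_x(self, seq):
        assert aac(seq).sum() == pytest.approx(100.0)

    def test_x_in_denominator_only(self):
        v = aac("AX")
        assert v[0] == pytest.approx(50.0) and v.sum() == pytest.approx(50.0)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            aac("")


class TestProteinKmer:
    def test_group1_homopolymer(self):
        v = protein_kmer("AAAA", 3)  # reduced '1111' -> '111' twice / N=4
        assert v[0] == pytest.approx(0.5)
        assert v[1:].sum() == 0

    def test_lengths(self):
        assert protein_kmer("MKVLATWY", 3).shape == (343,)
        assert protein_kmer("MKVLATWY", 4).shape == (2401,)

    def test_group_invariance(self):
        # A, G, V all belong to group 1
        np.testing.assert_allclose(protein_kmer("AGVAGV", 3), protein_kmer("VAGGAV", 3))

    @given(seq=clean_protein, k=st.sampled_from([3, 4]))
    @settings(max_examples=50, deadline=None)
    def test_matches_brute_force_on_reduced_sequence(self, seq, k):
        reduced = reduce_alphabet(seq)
        expected = brute_force_kmer_counts(reduced, "1234567", k) / len(seq)
        np.testing.assert_allclose(protein_kmer(seq, k), expected)


class TestOrf:
    def test_simple_orf_with_stop(self):
        start, length, has_stop = find_longest_orf("AUGAAAUAG")
        assert (start, length, has_stop) == (0, 9, True)

    def test_no_start_codon(self):
        assert find_longest_orf("CCCCCC") == (-1, 0, False)

    def test_stopless_orf_runs_to_frame_end(self):
        start, length, has_stop = find_longest_orf("AUGAAAAAA")
        assert (start, length, has_stop) == (0, 9, False)

    def test_require_stop_skips_stopless(self):
        assert find_longest_orf("AUGAAAAAA", require_stop=True) == (-1, 0, False)

    def test_longest_across_frames(self):
        # frame 1 ORF (offset 1) longer than frame 0's
        seq = "A" + "AUG" + "AAA" * 5 + "UAG"
        start, length, has_stop = find_longest_orf(seq)
        assert (start, length, has_stop) == (1, 21, True)


class TestRedFeatures:
    def test_full_coverage_orf(self):
        v = red_features("AUGAAAUAG")
        assert v[0] == 9.0 and v[1] == 1.0 and v[2] == 1.0

    def test_no_orf_sentinel(self):
        v = red_features("CCCCCC")
        assert (v[0], v[1], v[2]) == (0.0, 0.0, -1.0)
        assert v[5] == v[6] == v[7] == 0.0  # peptide slots

    def test_dimension(self):
        assert red_features("ACGUACGUACGU").shape == (RED_DIM,)
        assert RED_DIM == 38

    def test_ctd_composition_uniform(self):
        v = nucleotide_ctd("ACGU")
        np.testing.assert_allclose(v[:4], 0.25)

    def test_ctd_shape(self):
        assert nucleotide_ctd("ACGUACGU").shape == (30,)

    def test_hexamer_table_used(self):
        table = {"AAAAAA": 2.0}
        v = red_features("AAAAAAA", hexamer_table=table)
        assert v[4] == pytest.approx(2.0)
        assert red_features("AAAAAAA")[4] == 0.0

    def test_fickett_reasonable_range(self):
        s = fickett_score("ACGUACGUACGUACGAUGCUAGCUA")
        assert 0.0 < s < 2.0

    def test_deterministic(self):
        seq = "AUG" + "ACGU" * 30 + "UAG"
        np.testing.assert_array_equal(red_features(seq), red_features(seq))

    def test_coverage_denominator_changes_with_padding(self):
        seq = "AUGAAAUAG"
        padded = seq + "CCC"
        v, vp = red_features(seq), red_features(padded)
        assert v[0] == vp[0] == 9.0  # ORF length unchanged
        assert vp[1] == pytest.approx(9 / 12)  # coverage denominator grows


class TestAssembleHandcrafted:
    def test_a2_total_dimension(self, rng):
        hv = assemble_handcrafted("ACGU" * 30, "MKVLATWYH" * 5)
        assert hv.a2.shape == (20 + 343 + 2401,)

    def test_a1_layout(self):
        hv = assemble_handcrafted("ACGU" * 30, "MKVLATWYH" * 5)
        assert hv.a1.shape == (RED_DIM + 16 + 64,)
        assert hv.component("a1", "dnc").shape == (16,)

    def test_component_slices_reconstruct(self):
        rna, prot = "AUGACGUACGUUAG" * 3, "MKVLATWYHRKDE" * 4
        hv = assemble_handcrafted(rna, prot)
        np.testing.assert_allclose(hv.component("a1", "3mer"), rna_kmer(rna, 3))
        np.testing.assert_allclose(hv.component("a2", "aac"), aac(prot))
        np.testing.assert_allclose(hv.component("a2", "4mer"), protein_kmer(prot, 4))

    def test_frequency_vectors_non_negative(self):
        hv = assemble_handcrafted("ACGU" * 30, "MKVLATWYH" * 5)
        assert (hv.component("a1", "dnc") >= 0).all()
        assert (hv.a2 >= 0).all()


class TestEncoderRegistry:
    def test_builtin_encoders_registered(self):
        assert set(registered_encoders("lnc")) >= {"red", "dnc", "3mer"}
        assert set(registered_encoders("prot")) >= {"aac", "3mer", "4mer"}

    def test_plugin_registration(self):
        register_encoder("gc_content", lambda s: np.array([s.count("G") + s.count("C")]), "lnc")
        assert "gc_content" in registered_encoders("lnc")

    def test_reregistration_warns(self):
        register_encoder("tmp_enc", lambda s: np.zeros(1), "lnc")
        with pytest.warns(UserWarning, match="re-registered"):
            register_encoder("tmp_enc", lambda s: np.ones(1), "lnc")
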