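"""Encoder correctness against the brute-force oracles and their invariants."""

import numpy as np
import pytest

import abclass
from abclass.features import (PseAACConfig, encode_aac, encode_combined,
                              encode_dc, encode_dataset, encode_pseaac1,
                              encode_pseaac2, feature_names,
                              standardized_scale)

from oracles import (oracle_aac, oracle_combined, oracle_dc, oracle_pseaac1,
                     oracle_pseaac2)

CFG = PseAACConfig(lam=4, w=0.05)


class TestAAC:
    @pytest.mark.parametrize("seq, expected", [
        ("AAAAG", {"A": 0.8, "G": 0.2}),
        ("QQQQQ", {"Q": 1.0}),
        ("ACDEFGHIKLMNPQRSTVWY", {aa: 0.05 for aa in abclass.AMINO_ACIDS}),
    ])
    def test_known_compositions(self, seq, expected):
        v = encode_aac(seq)
        for i, aa in enumerate(abclass.AMINO_ACIDS):
            assert v[i] == pytest.approx(expected.get(aa, 0.0))

    def test_empty_sequence_is_error(self):
        with pytest.raises(ValueError):
            encode_aac("")

    def test_invariant_under_residue_permutation(self, rng):
        seq = "ACDEFGHIKLMNP"
        shuffled = "".join(rng.permutation(list(seq)))
        assert np.allclose(encode_aac(seq), encode_aac(shuffled))


class TestDC:
    def test_adjacent_pair_frequencies(self):
        v = encode_dc("AAG")
        names = feature_names("dc")
        d = dict(zip(names, v))
        assert d["dc:AA"] == pytest.approx(0.5)
        assert d["dc:AG"] == pytest.approx(0.5)
        assert sum(v) == pytest.approx(1.0)

    def test_homopolymer_activates_only_diagonal(self):
        v = encode_dc("QQQQQ")
        d = dict(zip(feature_names("dc"), v))
        assert d["dc:QQ"] == pytest.approx(1.0)
        assert sum(x for n, x in d.items() if n != "dc:QQ") == 0.0

    def test_pair_order_is_significant(self):
        d = dict(zip(feature_names("dc"), encode_dc("AG")))
        assert d["dc:AG"] == 1.0 and d["dc:GA"] == 0.0

    def test_too_short_is_error(self):
        with pytest.raises(ValueError):
            encode_dc("A")

    def test_generally_changes_under_permutation(self):
        assert not np.allclose(encode_dc("ACACAC"), encode_dc("AAACCC"))


class TestPseAAC:
    def test_property_scales_standardized(self):
        for name in ("hydrophobicity", "hydrophilicity", "sidechain_mass"):
            s = standardized_scale(name)
            assert s.mean() == pytest.approx(0.0, abs=1e-12)
            assert s.std() == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("encode", [encode_pseaac1, encode_pseaac2])
    def test_w_zero_reduces_to_aac(self, encode):
        cfg = PseAACConfig(lam=3, w=0.0)
        v = encode("ACDEFGH", cfg)
        assert np.allclose(v[:20], encode_aac("ACDEFGH"))
        assert np.allclose(v[20:], 0.0)

    def test_homopolymer_type1_reduces_to_aac_any_w(self):
        v = encode_pseaac1("QQQQQQ", PseAACConfig(lam=4, w=0.7))
        assert np.allclose(v[:20], encode_aac("QQQQQQ"))
        assert np.allclose(v[20:], 0.0)

    def test_vector_lengths(self):
        assert len(encode_pseaac1("ACDEF", PseAACConfig(lam=2))) == 22
        assert len(encode_pseaac2("ACDEF", PseAACConfig(lam=1))) == 22
        assert len(encode_pseaac2("ACDEF", PseAACConfig(lam=2))) == 24

    def test_lam_not_below_length_is_error(self):
        with pytest.raises(ValueError):
            encode_pseaac1("ACDEF", PseAACConfig(lam=5))

    def test_lam_zero_returns_plain_aac(self):
        v = encode_pseaac1("ACDEF", PseAACConfig(lam=0, w=0.05))
        assert np.allclose(v, encode_aac("ACDEF"))

    def test_type1_components_non_negative(self, random_peptides):
        for seq in random_peptides[:20]:
            assert (encode_pseaac1(seq, CFG) >= 0).all()


class TestOracleEquivalence:
    """All four encoders match the independent brute-force reference."""

    def test_all_encoders_on_random_peptides(self, random_peptides):
        for seq in random_peptides:
            assert np.allclose(encode_aac(seq), oracle_aac(seq), atol=1e-10)
            assert np.allclose(encode_dc(seq), oracle_dc(seq), atol=1e-10)
            assert np.allclose(encode_pseaac1(seq, CFG),
                               oracle_pseaac1(seq, CFG.lam, CFG.w), atol=1e-10)
            assert np.allclose(encode_pseaac2(seq, CFG),
                               oracle_pseaac2(seq, CFG.lam, CFG.w), atol=1e-10)

    def test_combined_matches_oracle(self):
        seq = "ACDEFGHIKLMNPQRSTVWY"
        assert np.allclose(encode_combined(seq, CFG),
                           oracle_combined(seq, CFG.lam, CFG.w), atol=1e-10)

    def test_rows_sum_to_one(self, random_peptides):
        for seq in random_peptides[:25]:
            for enc in (encode_aac(seq), encode_dc(seq),
                        encode_pseaac1(seq, CFG), encode_pseaac2(seq, CFG)):
                assert abs(enc.sum() - 1.0) < 1e-9


class TestEncodeDataset:
    def test_shapes_per_encoder(self, tiny_dataset):
        n = len(tiny_dataset)
        assert encode_dataset(tiny_dataset, "aac").shape == (n, 20)
        assert encode_dataset(tiny_dataset, "dc").shape == (n, 400)
        assert encode_dataset(tiny_dataset, "pseaac1", CFG).shape == (n, 24)
        assert encode_dataset(tiny_dataset, "pseaac2", CFG).shape == (n, 28)
        assert encode_dataset(tiny_dataset, "combined", CFG).shape == (n, 472)

    def test_deterministic(self, tiny_dataset):
        a = encode_dataset(tiny_dataset, "combined", CFG)
        b = encode_dataset(tiny_dataset, "combined", CFG)
        assert a.equals(b)

    def test_column_names_globally_unique_and_prefixed(self):
        names = feature_names("combined", CFG)
        assert len(names) == len(set(names)) == 472
        assert all(":" in n for n in names)

    def test_unknown_encoder_is_fatal(self, tiny_dataset):
        with pytest.raises(ValueError):
            encode_dataset(tiny_dataset, "kmer3")

    def test_row_order_follows_dataset(self, tiny_dataset):
        fm = encode_dataset(tiny_dataset, "aac")
        assert list(fm.index) == tiny_dataset.ids()
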