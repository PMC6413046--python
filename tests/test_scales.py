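import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import tripepqsar as tq
from tripepqsar.scales import (EXPECTED_K, EncodingError, ScaleRegistryError,
                               peptide_labels)

TRIPEPTIDES = st.text(alphabet=list(tq.AMINO_ACIDS), min_size=3, max_size=3)


class TestRegistry:
    def test_all_sixteen_scales_load_with_expected_dimensions(self):
        scales = tq.all_scales()
        assert [s.name for s in scales] == list(tq.REGISTRY_ORDER)
        for s in scales:
            assert s.k == EXPECTED_K[s.name]
            assert set(s.values) == set(tq.AMINO_ACIDS)
            assert all(len(v) == s.k for v in s.values.values())

    def test_total_properties_give_306_tripeptide_variables(self):
        assert sum(s.k for s in tq.all_scales()) == 102

    @pytest.mark.parametrize("name,k", [("Z-scale", 3), ("HESH", 12)])
    def test_get_scale_dimension(self, name, k):
        assert tq.get_scale(name).k == k

    def test_unknown_scale_lists_valid_identifiers(self):
        with pytest.raises(ScaleRegistryError, match="Z-scale"):
            tq.get_scale("XYZ")

    def test_repeated_calls_identical(self):
        assert tq.get_scale("VHSE") is tq.get_scale("VHSE")


class TestEncodePeptide:
    def test_tripeptide_gives_three_blocks_with_terminal_labels(self):
        z = tq.get_scale("Z-scale")
        values, labels = tq.encode_peptide("LHA", z)
        assert labels == ["N-Z-1", "N-Z-2", "N-Z-3", "M-Z-1", "M-Z-2",
                          "M-Z-3", "C-Z-1", "C-Z-2", "C-Z-3"]
        np.testing.assert_array_equal(values[:3], z.vector("L"))
        np.testing.assert_array_equal(values[3:6], z.vector("H"))
        np.testing.assert_array_equal(values[6:], z.vector("A"))

    @pytest.mark.parametrize("scale", ["Z-scale", "HSEHPCSV"])
    def test_homopeptide_blocks_identical(self, scale):
        s = tq.get_scale(scale)
        values, _ = tq.encode_peptide("AAA", s)
        blocks = values.reshape(3, s.k)
        np.testing.assert_array_equal(blocks[0], blocks[1])
        np.testing.assert_array_equal(blocks[1], blocks[2])

    def test_palindrome_has_equal_terminal_blocks(self):
        s = tq.get_scale("Z-scale")
        values, _ = tq.encode_peptide("YHY", s)
        np.testing.assert_array_equal(values[:3], values[6:])

    def test_unknown_residue_named_in_error(self):
        with pytest.raises(EncodingError, match="'X'"):
            tq.encode_peptide("AXA", tq.get_scale("Z-scale"))

    def test_too_short_sequence_rejected(self):
        with pytest.raises(EncodingError):
            tq.encode_peptide("A", tq.get_scale("Z-scale"))


class TestEncodeDataset:
    def test_full_registry_gives_306_columns(self, ftc):
        enc = ftc.encode()
        assert enc.X.shape == (214, 306)
        assert enc.variable_labels[0] == "N-Z-1"
        assert enc.variable_labels[305] == "C-HSEHPCSV-12"
        assert len(set(enc.variable_labels)) == 306

    def test_single_sequence_single_scale(self):
        enc = tq.encode_dataset(["LHA"], [1.0], [tq.get_scale("Z-scale")])
        assert enc.X.shape == (1, 9)

    def test_block_order_matches_per_peptide_encoding(self):
        scales = [tq.get_scale("VHSE"), tq.get_scale("ISA-ECI")]
        seqs = ["LHA", "YHY", "WWW", "ACD", "KYL"]
        enc = tq.encode_dataset(seqs, np.arange(5.0), scales)
        assert enc.X.shape == (5, 30)
        assert enc.variable_labels[:2] == ["N-VHSE-1", "N-VHSE-2"]
        assert enc.variable_labels[24] == "N-ISAECI-1"
        for i, seq in enumerate(seqs):
            expected = np.concatenate(
                [tq.encode_peptide(seq, s)[0] for s in scales]
            )
            np.testing.assert_array_equal(enc.X[i], expected)

    @settings(max_examples=25, deadline=None)
    @given(seqs=st.lists(TRIPEPTIDES, min_size=1, max_size=8),
           pick=st.sets(st.integers(0, 15), min_size=1, max_size=4))
    def test_rows_are_pure_lookups_and_p_is_3_sum_k(self, seqs, pick):
        scales = [tq.get_scale(tq.REGISTRY_ORDER[i]) for i in sorted(pick)]
        enc = tq.encode_dataset(seqs, np.zeros(len(seqs)), scales)
        assert enc.n_variables == 3 * sum(s.k for s in scales)
        for i, seq in enumerate(seqs):
            expected = np.concatenate(
                [tq.encode_peptide(seq, s)[0] for s in scales]
            )
            np.testing.assert_array_equal(enc.X[i], expected)

    def test_permuting_samples_permutes_rows_only(self):
        seqs = ["LHA", "YHY", "WWW", "ACD"]
        enc = tq.encode_dataset(seqs, np.arange(4.0),
                                [tq.get_scale("Z-scale")])
        perm = [2, 0, 3, 1]
        enc2 = tq.encode_dataset([seqs[i] for i in perm],
                                 np.arange(4.0)[perm],
                                 [tq.get_scale("Z-scale")])
        np.testing.assert_array_equal(enc2.X, enc.X[perm])
        assert enc2.variable_labels == enc.variable_labels

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="responses"):
            tq.encode_dataset(["LHA"], [1.0, 2.0], [tq.get_scale("Z-scale")])

    def test_csv_export_roundtrip(self, tmp_path):
        enc = tq.encode_dataset(["LHA", "YHY"], [1.0, 2.0],
                                [tq.get_scale("Z-scale")])
        path = tmp_path / "enc.csv"
        enc.to_csv(path)
        import pandas as pd

        df = pd.read_csv(path)
        assert list(df.columns) == ["sample_id"] + enc.variable_labels + ["activity"]
        np.testing.assert_allclose(df[enc.variable_labels].to_numpy(), enc.X)


def test_generic_longer_peptides_use_positional_labels():
    s = tq.get_scale("Z-scale")
    values, labels = tq.encode_peptide("ACDE", s)
    assert len(values) == 4 * s.k
    assert labels[0] == "P1-Z-1" and labels[-1] == "P4-Z-3"
    assert peptide_labels(s, 4)[3] == "P2-Z-1"
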