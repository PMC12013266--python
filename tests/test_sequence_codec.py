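"""Codec unit and property tests: parsing, encodings, normalization, splits."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from promodiff.sequence_codec import (
    ALPHABET,
    ConfigurationError,
    NormalizationParams,
    PromoterDataset,
    PromoterRecord,
    ValidationError,
    encode_dinucleotide_tokens,
    encode_position_tokens,
    encode_sequence_tokens,
    log_transform,
    minmax_denormalize,
    minmax_normalize,
    one_hot_decode,
    one_hot_encode,
    read_promoter_table,
    split_dataset,
    tss_position,
)

sequences = st.text(alphabet=ALPHABET, min_size=1, max_size=60)


# ---------------------------------------------------------------------------
# records and parsing


class TestRecords:
    def test_rejects_invalid_alphabet(self):
        with pytest.raises(ValidationError, match="ATNN|outside"):
            PromoterRecord("bad", "ATNN")

    def test_rejects_nonpositive_strength(self):
        with pytest.raises(ValidationError, match="strength"):
            PromoterRecord("bad", "ATCG", strength=0.0)

    def test_dataset_rejects_mixed_lengths(self):
        with pytest.raises(ValidationError, match="mixed lengths"):
            PromoterDataset(
                [PromoterRecord("a", "ATCG"), PromoterRecord("b", "ATC")]
            )

    def test_dataset_rejects_duplicate_ids(self):
        with pytest.raises(ValidationError, match="duplicate"):
            PromoterDataset(
                [PromoterRecord("a", "ATCG"), PromoterRecord("a", "GGCC")]
            )


class TestReaders:
    def test_csv_round_trip(self, tmp_path):
        path = tmp_path / "promoters.csv"
        path.write_text("id,sequence,strength\np1,ATCG,10\np2,GGCC,20\n")
        ds = read_promoter_table(path)
        assert len(ds) == 2
        assert ds.sequence_length == 4
        assert ds[0].sequence == "ATCG"
        assert ds[1].strength == 20.0

    def test_fasta_has_no_strengths(self, tmp_path):
        path = tmp_path / "seqs.fasta"
        path.write_text(">only\nACGT\n")
        ds = read_promoter_table(path)
        assert len(ds) == 1
        assert ds[0].strength is None

    def test_invalid_character_names_record(self, tmp_path):
        path = tmp_path / "promoters.csv"
        path.write_text("id,sequence,strength\nbadrec,ATNN,10\n")
        with pytest.raises(ValidationError, match="badrec"):
            read_promoter_table(path)

    def test_lenient_mode_drops_bad_records(self, tmp_path):
        path = tmp_path / "promoters.csv"
        path.write_text("id,sequence,strength\nok,ATCG,10\nbad,ATNN,5\n")
        ds = read_promoter_table(path, strict_alphabet=False)
        assert [r.id for r in ds] == ["ok"]

    def test_missing_column_is_configuration_error(self, tmp_path):
        path = tmp_path / "promoters.csv"
        path.write_text("id,dna,strength\np1,ATCG,10\n")
        with pytest.raises(ConfigurationError, match="sequence"):
            read_promoter_table(path)


# ---------------------------------------------------------------------------
# one-hot


class TestOneHot:
    def test_basis_vectors(self):
        assert one_hot_encode("A").tolist() == [[1, 0, 0, 0]]
        np.testing.assert_array_equal(one_hot_encode("ATCG"), np.eye(4))

    def test_decode_argmax_and_tie_break(self):
        assert one_hot_decode([[1, 0, 0, 0]]) == "A"
        assert one_hot_decode([[0.1, 0.2, 0.6, 0.1]]) == "C"
        assert one_hot_decode([[0.5, 0.5, 0, 0]]) == "A"  # tie → lowest channel

    def test_decode_rejects_wrong_width(self):
        with pytest.raises(ValidationError):
            one_hot_decode(np.zeros((3, 5)))

    @settings(max_examples=200, derandomize=True)
    @given(sequences)
    def test_round_trip(self, seq):
        assert one_hot_decode(one_hot_encode(seq)) == seq


# ---------------------------------------------------------------------------
# token streams


class TestTokens:
    def test_single_nucleotide_map(self):
        assert encode_sequence_tokens("G").tolist() == [3]
        assert encode_sequence_tokens("ATCG").tolist() == [0, 1, 2, 3]
        assert encode_sequence_tokens("AAAA").tolist() == [0, 0, 0, 0]

    def test_dinucleotide_map_exhaustive(self):
        # Row-major over (A,T,C,G) × (A,T,C,G): AA=4 … GG=19.
        expected = {}
        code = 4
        for first in ALPHABET:
            for second in ALPHABET:
                expected[first + second] = code
                code += 1
        for pair, want in expected.items():
            assert encode_dinucleotide_tokens(pair)[0] == want
        # padded pair codes A0..G0 = 20..23
        for i, base in enumerate(ALPHABET):
            assert encode_dinucleotide_tokens(base).tolist() == [20 + i]

    def test_dinucleotide_examples(self):
        assert encode_dinucleotide_tokens("AA").tolist() == [4, 20]
        assert encode_dinucleotide_tokens("G").tolist() == [23]

    @settings(max_examples=200, derandomize=True)
    @given(sequences)
    def test_streams_have_equal_length(self, seq):
        assert len(encode_dinucleotide_tokens(seq)) == len(seq)
        assert len(encode_sequence_tokens(seq)) == len(seq)
        assert len(encode_position_tokens(len(seq))) == len(seq)

    @settings(max_examples=200, derandomize=True)
    @given(sequences)
    def test_dinucleotide_agrees_with_sequence_tokens(self, seq):
        # The dinucleotide token at i determines the single-nucleotide token
        # at i: codes 4–19 encode 4*first+second, codes 20–23 encode first.
        seq_tok = encode_sequence_tokens(seq)
        din_tok = encode_dinucleotide_tokens(seq)
        for s, d in zip(seq_tok, din_tok):
            first = (d - 4) // 4 if d < 20 else d - 20
            assert first == s

    def test_position_tokens(self):
        assert encode_position_tokens(3).tolist() == [0, 1, 2]
        assert encode_position_tokens(1).tolist() == [0]
        assert encode_position_tokens(50).tolist() == list(range(50))
        with pytest.raises(ValidationError):
            encode_position_tokens(0)

    def test_tss_coordinate_convention(self):
        assert tss_position(49, 50) == -1
        assert tss_position(0, 50) == -50


# ---------------------------------------------------------------------------
# strength preprocessing


class TestNormalization:
    def test_log_transform_values(self):
        np.testing.assert_allclose(log_transform([100]), [2.0])
        np.testing.assert_allclose(log_transform([1]), [0.0])
        np.testing.assert_allclose(log_transform([10, 1000]), [1.0, 3.0])

    def test_log_transform_rejects_nonpositive(self):
        with pytest.raises(ValidationError, match="indices \\[1\\]"):
            log_transform([1.0, 0.0])

    def test_pseudocount_admits_zero(self):
        np.testing.assert_allclose(log_transform([0.0], pseudocount=1.0), [0.0])

    def test_minmax_endpoints(self):
        values, params = minmax_normalize([0.0, 1.0, 2.0])
        np.testing.assert_allclose(values, [0.0, 0.5, 1.0])
        assert params == NormalizationParams(0.0, 2.0)

    def test_minmax_rejects_constant(self):
        with pytest.raises(ValidationError):
            minmax_normalize([1.0, 1.0])

    @settings(max_examples=100, derandomize=True)
    @given(
        st.lists(st.integers(-500, 500), min_size=2, max_size=30, unique=True).map(
            lambda ints: [i / 10 for i in ints]
        )
    )
    def test_round_trip_and_endpoints(self, values):
        normalized, params = minmax_normalize(values)
        assert normalized.min() == 0.0
        assert normalized.max() == 1.0
        np.testing.assert_allclose(
            minmax_denormalize(normalized, params), values, atol=1e-9
        )

    @settings(max_examples=100, derandomize=True)
    @given(
        st.lists(st.integers(-500, 500), min_size=2, max_size=30, unique=True).map(
            lambda ints: [i / 10 for i in ints]
        ),
        st.floats(min_value=0.1, max_value=10),
        st.floats(min_value=-5, max_value=5),
    )
    def test_affine_invariance(self, values, a, b):
        x = np.asarray(values)
        base, _ = minmax_normalize(x)
        scaled, _ = minmax_normalize(a * x + b)
        np.testing.assert_allclose(base, scaled, atol=1e-6)

    def test_composition_preserves_ranking(self):
        strengths = np.array([3.0, 1.0, 100.0, 7.5])
        normalized, _ = minmax_normalize(log_transform(strengths))
        assert (np.argsort(normalized) == np.argsort(strengths)).all()


# ---------------------------------------------------------------------------
# splitting


class TestSplit:
    def _tiny(self, n=10):
        return PromoterDataset(
            [PromoterRecord(f"r{i}", "ATCGATCG") for i in range(n)]
        )

    def test_ratio_and_reproducibility(self):
        ds = self._tiny(10)
        train1, test1 = split_dataset(ds, 0.2, seed=42)
        train2, test2 = split_dataset(ds, 0.2, seed=42)
        assert (len(train1), len(test1)) == (8, 2)
        assert [r.id for r in train1] == [r.id for r in train2]
        assert [r.id for r in test1] == [r.id for r in test2]

    def test_partition_is_exhaustive_and_disjoint(self):
        ds = self._tiny(23)
        train, test = split_dataset(ds, 0.3, seed=1)
        train_ids = {r.id for r in train}
        test_ids = {r.id for r in test}
        assert train_ids | test_ids == {r.id for r in ds}
        assert not train_ids & test_ids

    def test_different_seeds_differ(self):
        ds = self._tiny(30)
        _, test_a = split_dataset(ds, 0.2, seed=0)
        _, test_b = split_dataset(ds, 0.2, seed=1)
        assert {r.id for r in test_a} != {r.id for r in test_b}

    def test_fraction_bounds(self):
        with pytest.raises(ConfigurationError):
            split_dataset(self._tiny(), 1.5)
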