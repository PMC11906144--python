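import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from odorcascade.io import ReceptorRecord
from odorcascade.protfeats import (
    AMINO_ACIDS,
    AlignmentMatrix,
    KmerVocabulary,
    alignment_onehot,
    featurize_receptors,
    kmer_counts,
    kmer_proportions,
)

sequences = st.text(alphabet=AMINO_ACIDS, min_size=3, max_size=60)


class TestKmerCounts:
    def test_frozen_examples(self):
        v1 = KmerVocabulary(1)
        c1 = kmer_counts("AAG", 1)
        assert c1[v1.index("A")] == 2 and c1[v1.index("G")] == 1
        assert c1.sum() == 3

        v2 = KmerVocabulary(2)
        c2 = kmer_counts("AAG", 2)
        assert c2[v2.index("AA")] == 1 and c2[v2.index("AG")] == 1
        assert c2.sum() == 2

        v3 = KmerVocabulary(3)
        c3 = kmer_counts("AAG", 3)
        assert c3[v3.index("AAG")] == 1
        assert c3.sum() == 1

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(seq=sequences, k=st.integers(1, 3))
    def test_count_conservation(self, seq, k):
        counts = kmer_counts(seq, k)
        assert counts.sum() == len(seq) - k + 1
        assert len(counts) == 20**k

    def test_shuffle_invariance_only_for_k1(self):
        # single-residue composition ignores order; adjacent pairs do not
        a = kmer_counts("AGWK", 1)
        b = kmer_counts("KWGA", 1)
        assert np.array_equal(a, b)
        assert not np.array_equal(kmer_counts("AG", 2), kmer_counts("GA", 2))

    def test_errors(self):
        with pytest.raises(ValueError, match="shorter"):
            kmer_counts("AG", 3)
        with pytest.raises(ValueError, match=r"'X' at position 2"):
            kmer_counts("AGXW", 1)
        with pytest.raises(ValueError, match="positive"):
            kmer_counts("AG", 0)


class TestKmerProportions:
    def test_frozen_examples(self):
        v1 = KmerVocabulary(1)
        p1 = kmer_proportions("AAG", 1)
        assert p1[v1.index("A")] == pytest.approx(2 / 3)
        assert p1[v1.index("G")] == pytest.approx(1 / 3)
        p2 = kmer_proportions("AAAA", 2)
        assert p2[KmerVocabulary(2).index("AA")] == pytest.approx(1.0)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(seq=sequences, k=st.integers(1, 3))
    def test_normalization(self, seq, k):
        assert kmer_proportions(seq, k).sum() == pytest.approx(1.0, abs=1e-9)


class TestAlignment:
    def test_onehot_shape_and_validity(self):
        aln = AlignmentMatrix(["r1", "r2"], ["A-", "AA"])
        block = alignment_onehot(aln)
        assert block.values.shape == (2, 2 * 21)
        assert np.all(block.values.sum(axis=1) == 2)
        # each 21-wide position block carries exactly one indicator
        per_block = block.values.reshape(2, 2, 21).sum(axis=2)
        assert np.all(per_block == 1)
        # the gap slot of r1 position 1 is set
        assert block.values[0, 1 * 21 + 20] == 1.0

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError, match="unequal"):
            AlignmentMatrix(["r1", "r2"], ["A", "AG"])

    def test_unknown_symbol_rejected(self):
        with pytest.raises(ValueError, match="unknown symbol"):
            AlignmentMatrix(["r1"], ["A?"])

    def test_all_gap_row_rejected(self):
        with pytest.raises(ValueError, match="all gaps"):
            AlignmentMatrix(["r1", "r2"], ["--", "AA"])


class TestFeaturizeReceptors:
    def setup_method(self):
        self.receptors = [
            ReceptorRecord("r1", "ACDEFGHIKL"),
            ReceptorRecord("r2", "AAAAAAAAAA"),
            ReceptorRecord("r3", "WYWYWYWYWY"),
        ]

    @pytest.mark.parametrize(
        "variant,n_cols",
        [("1AAF", 20), ("2AAF", 400), ("3AAF", 8000),
         ("1AAFperc", 20), ("2AAFperc", 400), ("3AAFperc", 8000)],
    )
    def test_kaaf_dimensions(self, variant, n_cols):
        block = featurize_receptors(self.receptors, variant)
        assert block.values.shape == (3, n_cols)
        if variant.endswith("perc"):
            np.testing.assert_allclose(block.values.sum(axis=1), 1.0, atol=1e-9)

    def test_alignment_variant_requires_alignment(self):
        with pytest.raises(ValueError, match="alignment"):
            featurize_receptors(self.receptors, "alignment")

    def test_alignment_variant_row_order_follows_receptors(self):
        aln = AlignmentMatrix(
            ["r3", "r1", "r2"],
            ["WYWYWYWYWY", "ACDEFGHIKL", "AAAAAAAAAA"],
        )
        block = featurize_receptors(self.receptors, "alignment", aln)
        assert block.row_ids == ["r1", "r2", "r3"]
        assert block.values.shape == (3, 10 * 21)

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError, match="unknown variant"):
            featurize_receptors(self.receptors, "4AAF")


def test_vocabulary_is_lexicographic():
    v = KmerVocabulary(2)
    assert len(v) == 400
    assert v.kmers[0] == "AA"
    assert v.kmers[-1] == "YY"
    assert v.kmers[v.index("CW")] == "CW"
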