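"""Structural annotation: pair effects, variant calling, label parsing."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from mttrnascreen.catalog import NoGeneHitError
from mttrnascreen.io import annotation_agreement
from mttrnascreen.variants import (
    PairEffect,
    ReferenceMismatchError,
    Variant,
    annotate_variant,
    basepair_effect,
    call_variants,
)

BASES = "ACGT"


class TestBasepairEffect:
    @pytest.mark.parametrize(
        "ref,alt,partner,expected",
        [
            ("C", "T", "G", PairEffect.DISRUPTED),  # C-G -> U.G wobble
            ("T", "C", "G", PairEffect.CREATED),    # U.G wobble -> C-G
            ("A", "G", None, PairEffect.NONE),      # loop position
            ("A", "G", "T", PairEffect.DISRUPTED),
            ("A", "C", "C", PairEffect.NONE),       # neither allele pairs
            ("G", "T", "G", PairEffect.NONE),       # G.G -> U.G wobble: still unpaired
        ],
    )
    def test_examples(self, ref, alt, partner, expected):
        assert basepair_effect(ref, alt, partner) == expected

    def test_wobble_is_not_watson_crick(self):
        """A change into or out of a G.U wobble is a pairing change."""
        assert basepair_effect("C", "T", "G") is PairEffect.DISRUPTED
        assert basepair_effect("G", "A", "T") is PairEffect.CREATED

    @given(
        ref=st.sampled_from(BASES), alt=st.sampled_from(BASES),
        partner=st.sampled_from(BASES),
    )
    def test_antisymmetric_under_allele_swap(self, ref, alt, partner):
        if ref == alt:
            return
        forward = basepair_effect(ref, alt, partner)
        backward = basepair_effect(alt, ref, partner)
        swap = {
            PairEffect.CREATED: PairEffect.DISRUPTED,
            PairEffect.DISRUPTED: PairEffect.CREATED,
            PairEffect.NONE: PairEffect.NONE,
        }
        assert backward == swap[forward]

    def test_invalid_base_rejected(self):
        with pytest.raises(ValueError):
            basepair_effect("N", "A", "T")


class TestAnnotateVariant:
    @pytest.mark.parametrize(
        "label,gene,position,element,effect,pair",
        [
            ("m.7544C>T", "tRNA-Asp", 30, "Anticodon stem", PairEffect.DISRUPTED, "C-G"),
            ("m.7543A>G", "tRNA-Asp", 29, "Anticodon stem", PairEffect.DISRUPTED, "A-T"),
            ("m.8343A>G", "tRNA-Lys", 54, "TψC loop", PairEffect.NONE, ""),
            ("m.4395T>C", "tRNA-Gln", 6, "Acceptor arm", PairEffect.CREATED, "C-G"),
            ("m.5802G>A", "tRNA-Cys", 30, "Anticodon stem", PairEffect.DISRUPTED, "G-C"),
        ],
    )
    def test_examples(self, catalog, label, gene, position, element, effect, pair):
        ann = annotate_variant(catalog, Variant.from_label(label))
        assert ann.gene == gene
        assert ann.trna_position == position
        assert ann.element == element
        assert ann.pair_effect == effect
        assert ann.pair_string == pair

    def test_outside_trna_genes(self, catalog):
        with pytest.raises(NoGeneHitError):
            annotate_variant(catalog, Variant(position=3107, ref="A", alt="G"))

    def test_reference_mismatch(self, catalog):
        # 7544 reference is C; claiming A signals a wrong coordinate/strand
        with pytest.raises(ReferenceMismatchError):
            annotate_variant(catalog, Variant(position=7544, ref="A", alt="G"))

    def test_l_strand_alleles_are_rcrs_terms(self, catalog):
        """L-strand variants state rCRS alleles; tRNA-sense is internal."""
        ann = annotate_variant(catalog, Variant.from_label("m.5802G>A"))
        assert ann.variant.ref == "G"  # echoed as given
        with pytest.raises(ReferenceMismatchError):
            # the tRNA-sense (complemented) allele must be rejected as input
            annotate_variant(catalog, Variant(position=5802, ref="C", alt="T"))


def test_study_table_watson_crick_arrows(catalog, study_table):
    """The eight paired-position variants reproduce the printed arrows; the
    single rendering disagreement (7492 pair-string letter order) is reported,
    not silently passed."""
    agree = annotation_agreement(catalog, study_table)
    assert agree["gene_match"].all()
    assert agree["numbering_match"].all()
    assert agree["element_match"].all()
    assert agree["arrow_match"].all()
    mismatched = set(agree.loc[~agree["pair_string_match"], "mutation"])
    assert mismatched == {"7492C>T"}


class TestCallVariants:
    def test_single_planted_mismatch(self):
        assert call_variants("ACGT", "ACTT", 101) == [Variant(103, "G", "T")]

    def test_identity_and_order(self):
        assert call_variants("ACGTACGT", "ACGTACGT", 1) == []
        out = call_variants("AAAA", "ATAG", 10)
        assert [v.label for v in out] == ["m.11A>T", "m.13A>G"]

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            call_variants("ACGT", "ACG", 1)

    def test_non_acgt_skipped(self):
        assert call_variants("ANGT", "ACGT", 1) == []
        assert call_variants("ACGT", "NCTT", 1) == [Variant(3, "G", "T")]


class TestVariantLabels:
    @pytest.mark.parametrize("label", ["m.7544C>T", "7544C>T", " m.7544C>T "])
    def test_parse_variants(self, label):
        v = Variant.from_label(label)
        assert (v.position, v.ref, v.alt) == (7544, "C", "T")
        assert v.label == "m.7544C>T"

    @pytest.mark.parametrize("label", ["m.7544C>C", "m.7544CC>T", "rubbish", "m.0A>G"])
    def test_bad_labels_rejected(self, label):
        with pytest.raises(ValueError):
            Variant.from_label(label)
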