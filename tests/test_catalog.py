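"""Reference model: gene catalog, coordinate mapping, cloverleaf tables."""

import pytest

from mttrnascreen.catalog import (
    Catalog,
    CatalogError,
    CloverleafEntry,
    CloverleafMap,
    NoGeneHitError,
    TRNAGene,
    load_catalog,
    locate,
    trna_position,
    write_catalog,
)


def test_bundled_catalog_has_22_genes(catalog):
    assert len(catalog.genes) == 22
    assert len(catalog.maps) == 22


def test_partner_symmetry_all_maps(catalog):
    """partner(partner(p)) == p for every paired position in every gene."""
    for m in catalog.maps:
        paired = {e.position_number: e.partner for e in m.entries if e.partner is not None}
        assert paired, f"{m.gene} has no annotated pairs"
        for num, partner in paired.items():
            assert paired[partner] == num, f"{m.gene}: {num}<->{partner} asymmetric"


def test_anticodon_stem_pairing_trna_asp(catalog):
    """Canonical anticodon stem: 27-31 pair with 43-39; 30 pairs 40."""
    m = catalog.map_for("tRNA-Asp")
    pairs = {e.position_number: e.partner for e in m.entries if e.partner is not None}
    for p5, p3 in zip(range(27, 32), range(43, 38, -1)):
        assert pairs[p5] == p3
    elements = {e.position_number: e.element for e in m.entries}
    for num in (27, 28, 29, 30, 31, 39, 40, 41, 42, 43):
        assert elements[num] == "Anticodon stem"


def test_anticodon_stem_partners_also_stem(catalog):
    for m in catalog.maps:
        by_num = {e.position_number: e for e in m.entries}
        for e in m.entries:
            if e.element == "Anticodon stem" and e.partner is not None:
                assert by_num[e.partner].element == "Anticodon stem", (
                    f"{m.gene}: {e.position_number} pairs outside the stem"
                )


def test_sequences_match_spans(catalog):
    for g in catalog.genes:
        assert len(g.sequence) == g.end - g.start + 1


@pytest.mark.parametrize(
    "pos,gene",
    [(7544, "tRNA-Asp"), (8343, "tRNA-Lys"), (3243, "tRNA-Leu(UUR)"), (5831, "tRNA-Tyr")],
)
def test_locate_finds_gene(catalog, pos, gene):
    assert locate(catalog, pos).gene.name == gene


def test_locate_first_base_offset_and_l_strand(catalog):
    for g in catalog.genes:
        five_prime = g.start if g.strand == "H" else g.end
        assert locate(catalog, five_prime).offset == 1
        three_prime = g.end if g.strand == "H" else g.start
        assert locate(catalog, three_prime).offset == g.length


def test_locate_outside_trna_genes(catalog):
    with pytest.raises(NoGeneHitError):
        locate(catalog, 3107)  # rRNA/spacer region
    with pytest.raises(ValueError):
        locate(catalog, 20000)


@pytest.mark.parametrize(
    "gene,pos,number,element,partner",
    [
        ("tRNA-Asp", 7544, 30, "Anticodon stem", 40),
        ("tRNA-Asp", 7543, 29, "Anticodon stem", 41),
        ("tRNA-Leu(UUR)", 3302, 71, "Acceptor arm", 2),
        ("tRNA-Lys", 8343, 54, "TψC loop", None),
        ("tRNA-Gln", 4363, 38, "Anticodon stem", None),
    ],
)
def test_trna_position_examples(catalog, gene, pos, number, element, partner):
    info = trna_position(catalog, gene, pos)
    assert info.trna_position == number
    assert info.element == element
    assert info.partner == partner


def test_trna_position_ref_base_consistency(catalog):
    """ref_base always equals the catalog sequence at the mapped index."""
    for g in catalog.genes:
        for offset in (1, g.length // 2, g.length):
            pos = g.genomic_pos_of(offset)
            info = trna_position(catalog, g.name, pos)
            assert info.ref_base == g.sequence[offset - 1]


def test_trna_position_outside_gene(catalog):
    with pytest.raises(NoGeneHitError):
        trna_position(catalog, "tRNA-Asp", 8343)


def test_round_trip_write_then_load(catalog, tmp_path):
    out = tmp_path / "catalog.tsv"
    write_catalog(catalog, out, header=["round-trip copy"])
    reloaded = load_catalog(out)
    assert reloaded.genes == catalog.genes
    assert [m.entries for m in reloaded.maps] == [m.entries for m in catalog.maps]


def _toy_gene(seq="ACGTACGTAC"):
    return TRNAGene(name="tRNA-Toy", start=101, end=100 + len(seq), strand="H", sequence=seq)


def test_asymmetric_partner_rejected():
    entries = [
        CloverleafEntry(30, 1, "Anticodon stem", 40),
        CloverleafEntry(40, 2, "Anticodon stem", 29),  # asymmetric
        CloverleafEntry(29, 3, "Anticodon stem", None),
    ]
    with pytest.raises(CatalogError, match="asymmetric"):
        CloverleafMap(gene="tRNA-Toy", entries=tuple(entries))


def test_sequence_span_mismatch_rejected():
    with pytest.raises(CatalogError, match="span"):
        TRNAGene(name="tRNA-Bad", start=101, end=120, strand="H", sequence="ACGT")


def test_incomplete_position_table_rejected():
    gene = _toy_gene()
    entries = tuple(
        CloverleafEntry(i, i, "D-arm", None) for i in range(1, gene.length)
    )  # one index short
    with pytest.raises(CatalogError, match="cover"):
        Catalog(genes=(gene,), maps=(CloverleafMap(gene="tRNA-Toy", entries=entries),))


def test_load_error_names_gene_and_line(tmp_path):
    bad = tmp_path / "bad.tsv"
    bad.write_text("gene\ttRNA-Bad\t101\t120\tH\tACGT\n")
    with pytest.raises(CatalogError, match="bad.tsv:1"):
        load_catalog(bad)
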