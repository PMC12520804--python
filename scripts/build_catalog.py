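"""Author the bundled synthetic mt-tRNA reference catalog.

Writes ``src/mttrnascreen/data/mt_trna_catalog.synthetic.tsv``.  Gene
coordinates and strands follow the standard rCRS (NC_012920.1) annotation,
with two 1-3 bp boundary adjustments so genes are pairwise disjoint
(tRNA-Gln starts at 4332, tRNA-Tyr at 5827).  Cloverleaf numbering, element
assignments and pairing tables are curated per gene to the mitotRNAdb-style
convention used by the bundled study variant table.

Sequences are SYNTHETIC: every position named in the study variant table
carries its documented rCRS reference allele (strand-corrected for L-strand
genes), every annotated stem pair whose bases the table constrains carries
those bases, every other annotated pair is Watson-Crick complementary, and
the remaining positions are seeded-random.  Real rCRS sequence is not
reproduced and must not be assumed.

Run from the repository root:  python scripts/build_catalog.py
"""

from __future__ import annotations

import random
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from mttrnascreen.catalog import (  # noqa: E402
    Catalog,
    CloverleafEntry,
    CloverleafMap,
    TRNAGene,
    complement,
    load_catalog,
    write_catalog,
)

OUT = Path(__file__).resolve().parents[1] / "src" / "mttrnascreen" / "data" / \
    "mt_trna_catalog.synthetic.tsv"

SEED = 20251001


def r(a: int, b: int) -> list[int]:
    return list(range(a, b + 1))


# Per-gene definition: rCRS start, end, strand, ordered position-number list
# (length == gene span).  Duplicate numbers mark loop insertions (never paired).
GENES: dict[str, tuple[int, int, str, list[int]]] = {
    "tRNA-Phe":      (577, 647, "H", r(1, 71)),
    "tRNA-Val":      (1602, 1670, "H", r(1, 44) + r(49, 73)),
    "tRNA-Leu(UUR)": (3230, 3304, "H", r(1, 17) + [17, 17] + r(18, 73)),
    "tRNA-Ile":      (4263, 4331, "H", r(1, 44) + r(49, 73)),
    "tRNA-Gln":      (4332, 4400, "L", r(1, 44) + r(49, 73)),
    "tRNA-Met":      (4402, 4469, "H", r(1, 16) + r(18, 44) + r(49, 73)),
    "tRNA-Trp":      (5512, 5579, "H", r(1, 20) + r(22, 44) + r(49, 73)),
    "tRNA-Ala":      (5587, 5655, "L", r(1, 44) + r(49, 73)),
    "tRNA-Asn":      (5657, 5729, "L", r(1, 73)),
    "tRNA-Cys":      (5761, 5826, "L", r(1, 16) + r(22, 71)),
    "tRNA-Tyr":      (5827, 5891, "L", r(1, 65)),
    "tRNA-Ser(UCN)": (7446, 7514, "L", r(1, 17) + r(21, 72)),
    "tRNA-Asp":      (7518, 7585, "H", r(1, 14) + r(18, 71)),
    "tRNA-Lys":      (8295, 8364, "H", r(1, 16) + r(18, 44) + r(49, 60) + [60, 60] + r(61, 73)),
    "tRNA-Gly":      (9991, 10058, "H", r(1, 13) + r(17, 47) + r(49, 72)),
    "tRNA-Arg":      (10405, 10469, "H", r(1, 16) + r(18, 44) + r(49, 70)),
    "tRNA-His":      (12138, 12206, "H", r(1, 44) + r(49, 73)),
    "tRNA-Ser(AGY)": (12207, 12265, "H", r(1, 9) + r(24, 73)),
    "tRNA-Leu(CUN)": (12266, 12336, "H", r(1, 71)),
    "tRNA-Glu":      (14674, 14742, "L", r(1, 8) + r(10, 16) + r(18, 44) + r(47, 73)),
    "tRNA-Thr":      (15888, 15953, "H", r(1, 17) + r(20, 45) + r(47, 69)),
    "tRNA-Pro":      (15956, 16023, "L", r(1, 16) + r(18, 44) + r(49, 73)),
}

# The study table inverts tRNA-sense numbering order for two tRNA-Ala T-arm
# positions (rCRS 5603 -> 61, 5601 -> 59); swap the default labels 57/61.
ALA_SWAP = (53, 57)  # sequence indices whose numbers are exchanged

# element overrides: gene -> {position_number: element}
ELEMENT_OVERRIDES: dict[str, dict[int, str]] = {
    "tRNA-Gln": {38: "Anticodon stem"},
    "tRNA-Ser(UCN)": {26: "Anticodon stem", 44: "Anticodon stem"},
    "tRNA-Ser(AGY)": {42: "Acceptor arm"},
}

# pairs removed from the canonical set: gene -> {(5'number, 3'number), ...}
PAIR_EXCLUDE: dict[str, set[tuple[int, int]]] = {
    "tRNA-Thr": {(13, 22)},          # 15900/15907 rows carry no pairing annotation
    "tRNA-Ala": {(53, 61)},          # swapped labels; both left unpaired
    "tRNA-Ser(AGY)": {(28, 42)},     # 42 annotated Acceptor arm, unpaired, per table
}

# pairs added beyond the canonical set
PAIR_EXTRA: dict[str, set[tuple[int, int]]] = {
    "tRNA-Leu(UUR)": {(26, 44)},     # 3275 row pairs the variable-region base
    "tRNA-Ser(UCN)": {(26, 44)},     # 7492 row: extended anticodon stem
}

# tRNA-sense base constraints, keyed by position number.  Variant reference
# alleles from the study table (complemented for L-strand genes) plus the
# partner bases its pairing annotations imply.
BASES: dict[str, dict[int, str]] = {
    "tRNA-Phe": {20: "T", 58: "T"},
    "tRNA-Val": {61: "T", 53: "C"},
    "tRNA-Leu(UUR)": {71: "A", 44: "C", 59: "T", 2: "T", 26: "A"},
    "tRNA-Ile": {15: "T", 54: "C"},
    "tRNA-Gln": {38: "A", 6: "A", 67: "C"},
    "tRNA-Met": {58: "T"},
    "tRNA-Trp": {20: "A", 61: "T", 53: "C"},
    "tRNA-Ala": {59: "G", 61: "C"},
    "tRNA-Asn": {19: "T"},
    "tRNA-Cys": {30: "C", 16: "A", 6: "C", 40: "G", 66: "G"},
    "tRNA-Ser(UCN)": {26: "G", 17: "G", 44: "T"},
    "tRNA-Asp": {29: "A", 30: "C", 41: "T", 40: "G"},
    "tRNA-Lys": {54: "A"},
    "tRNA-Gly": {20: "T", 44: "T", 53: "A", 61: "A"},
    "tRNA-Arg": {55: "T"},
    "tRNA-His": {16: "C", 55: "T", 56: "T"},
    "tRNA-Ser(AGY)": {42: "A", 54: "C"},
    "tRNA-Leu(CUN)": {15: "A"},
    "tRNA-Glu": {54: "T", 18: "A"},
    "tRNA-Thr": {13: "T", 17: "C", 22: "A", 45: "G", 54: "C"},
    "tRNA-Pro": {59: "A", 7: "T", 66: "C"},
}


def element_for(num: int) -> str:
    if 1 <= num <= 7 or num >= 66:
        return "Acceptor arm"
    if 8 <= num <= 26:
        return "D-arm"
    if 27 <= num <= 31 or 39 <= num <= 43:
        return "Anticodon stem"
    if 32 <= num <= 38:
        return "Anticodon loop"
    if 44 <= num <= 48:
        return "Variable region"
    return "TψC loop"  # 49..65


CANONICAL_PAIRS = (
    [(k, 73 - k) for k in range(1, 8)]            # acceptor stem
    + [(10, 25), (11, 24), (12, 23), (13, 22)]    # D stem
    + [(27, 43), (28, 42), (29, 41), (30, 40), (31, 39)]  # anticodon stem
    + [(49, 65), (50, 64), (51, 63), (52, 62), (53, 61)]  # T stem
)


def build_gene(name: str, rng: random.Random) -> tuple[TRNAGene, CloverleafMap]:
    start, end, strand, numbers = GENES[name]
    length = end - start + 1
    assert len(numbers) == length, f"{name}: {len(numbers)} numbers for {length} nt"

    if name == "tRNA-Ala":
        i, j = (k - 1 for k in ALA_SWAP)
        numbers = list(numbers)
        numbers[i], numbers[j] = numbers[j], numbers[i]

    counts: dict[int, int] = {}
    for n in numbers:
        counts[n] = counts.get(n, 0) + 1
    unique_index = {n: i + 1 for i, n in enumerate(numbers) if counts[n] == 1}

    pairs = [p for p in CANONICAL_PAIRS if p not in PAIR_EXCLUDE.get(name, set())]
    pairs += sorted(PAIR_EXTRA.get(name, set()))
    pairs = [
        (p5, p3) for p5, p3 in pairs if p5 in unique_index and p3 in unique_index
    ]
    partner: dict[int, int] = {}
    for p5, p3 in pairs:
        partner[p5] = p3
        partner[p3] = p5

    # sequence: seeded random, then point constraints, then complement fill
    seq = [rng.choice("ACGT") for _ in range(length)]
    constrained = set()
    for num, base in BASES.get(name, {}).items():
        idx = unique_index[num]
        seq[idx - 1] = base
        constrained.add(idx)
    for p5, p3 in pairs:
        i3 = unique_index[p3]
        if i3 not in constrained:
            seq[i3 - 1] = complement(seq[unique_index[p5] - 1])

    overrides = ELEMENT_OVERRIDES.get(name, {})
    entries = []
    for i, num in enumerate(numbers, 1):
        elem = overrides.get(num, element_for(num))
        entries.append(
            CloverleafEntry(
                position_number=num,
                seq_index=i,
                element=elem,
                partner=partner.get(num) if counts[num] == 1 else None,
            )
        )
    gene = TRNAGene(name=name, start=start, end=end, strand=strand, sequence="".join(seq))
    return gene, CloverleafMap(gene=name, entries=tuple(entries))


def main() -> None:
    rng = random.Random(SEED)
    genes, maps = [], []
    for name in GENES:
        g, m = build_gene(name, rng)
        genes.append(g)
        maps.append(m)
    catalog = Catalog(genes=tuple(genes), maps=tuple(maps))
    OUT.parent.mkdir(parents=True, exist_ok=True)
    write_catalog(
        catalog,
        OUT,
        header=[
            "SYNTHETIC mt-tRNA reference catalog (mttrnascreen bundled fixture).",
            "Coordinates/strands: standard rCRS annotation (Gln 4332, Tyr 5827 adjusted",
            "for disjointness).  Sequences are synthetic: faithful at every position",
            "constrained by the bundled study variant table, seeded-random elsewhere.",
            "Do not use as real NC_012920.1 sequence.",
            "Records: gene<TAB>name start end strand sequence",
            "         pos<TAB>gene position_number seq_index element partner|.",
        ],
    )
    # round-trip validation
    load_catalog(OUT)
    print(f"wrote {OUT} ({OUT.stat().st_size} bytes, {len(genes)} genes)")


if __name__ == "__main__":
    main()
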