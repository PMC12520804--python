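"""Reference model for the 22 human mitochondrial tRNA genes.

The catalog ties 1-based rCRS genomic coordinates to tRNA-level structure:
each gene carries its coordinates, strand and tRNA-sense sequence, plus an
explicit cloverleaf position table mapping every sequence index to a
mitotRNAdb-style position number, a structural element and (for stem
positions) the position number of the paired base.

Cloverleaf numbering is deliberately data rather than algorithm: mammalian
mt-tRNAs have truncated D- and T-arms and irregular variable regions, so
canonical numbering cannot be derived reliably from sequence alone.  The
bundled default catalog (``data/mt_trna_catalog.synthetic.tsv``) uses
standard rCRS gene coordinates and strands; its sequences are synthetic,
constrained to carry the documented reference allele at every position the
bundled study variant table names and complementary bases across every
annotated stem pair (see the catalog file header and docs/methods.md).

All coordinates are 1-based inclusive rCRS; no 0-based interface is exposed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Iterable

__all__ = [
    "ELEMENTS",
    "MT_GENOME_LENGTH",
    "TRNAGene",
    "CloverleafEntry",
    "CloverleafMap",
    "GeneHit",
    "PositionInfo",
    "Catalog",
    "CatalogError",
    "NoGeneHitError",
    "load_catalog",
    "write_catalog",
    "default_catalog",
    "locate",
    "trna_position",
]

MT_GENOME_LENGTH = 16569

#: Structural element vocabulary.  Stem halves of the D- and TψC arms carry the
#: arm's element label (there is no separate stem label in this scheme, which is
#: also how the study table labels stem positions such as 13 or 61).
ELEMENTS = (
    "Acceptor arm",
    "D-arm",
    "Anticodon stem",
    "Anticodon loop",
    "Variable region",
    "TψC loop",
)

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def complement(base: str) -> str:
    """Complement of a single DNA base."""
    try:
        return _COMPLEMENT[base]
    except KeyError:
        raise ValueError(f"invalid base {base!r}") from None


def reverse_complement(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


class CatalogError(ValueError):
    """A catalog file failed validation; the message names the gene."""


class NoGeneHitError(LookupError):
    """A genomic position falls outside every tRNA gene in the catalog."""


@dataclass(frozen=True)
class TRNAGene:
    """One mt-tRNA gene on the rCRS.

    ``sequence`` is stored in tRNA sense: for H-strand genes it equals the
    rCRS slice, for L-strand genes it is the reverse complement of the slice,
    so index 1 is always the tRNA 5' end.
    """

    name: str
    start: int
    end: int
    strand: str  # "H" or "L"
    sequence: str

    def __post_init__(self) -> None:
        if self.strand not in ("H", "L"):
            raise CatalogError(f"{self.name}: strand must be H or L, got {self.strand!r}")
        if not (1 <= self.start <= self.end <= MT_GENOME_LENGTH):
            raise CatalogError(f"{self.name}: bad coordinates {self.start}..{self.end}")
        if len(self.sequence) != self.length:
            raise CatalogError(
                f"{self.name}: sequence length {len(self.sequence)} does not match "
                f"span {self.start}..{self.end} ({self.length} nt)"
            )
        bad = set(self.sequence) - set("ACGT")
        if bad:
            raise CatalogError(f"{self.name}: non-ACGT characters {sorted(bad)}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, genomic_pos: int) -> bool:
        return self.start <= genomic_pos <= self.end

    def offset_of(self, genomic_pos: int) -> int:
        """1-based tRNA-sense offset of an rCRS coordinate within the gene.

        L-strand genes count from the gene's 3'-most rCRS coordinate (the
        gene end), which is the tRNA 5' end.
        """
        if not self.contains(genomic_pos):
            raise NoGeneHitError(f"{genomic_pos} not in {self.name}")
        if self.strand == "H":
            return genomic_pos - self.start + 1
        return self.end - genomic_pos + 1

    def genomic_pos_of(self, offset: int) -> int:
        if not 1 <= offset <= self.length:
            raise ValueError(f"{self.name}: offset {offset} outside 1..{self.length}")
        if self.strand == "H":
            return self.start + offset - 1
        return self.end - offset + 1

    def sense_base(self, genomic_pos: int) -> str:
        return self.sequence[self.offset_of(genomic_pos) - 1]


@dataclass(frozen=True)
class CloverleafEntry:
    position_number: int
    seq_index: int  # 1-based index into the gene's tRNA-sense sequence
    element: str
    partner: int | None  # position number of the paired base


@dataclass(frozen=True)
class GeneHit:
    gene: TRNAGene
    offset: int


@dataclass(frozen=True)
class PositionInfo:
    trna_position: int
    element: str
    partner: int | None
    ref_base: str  # tRNA-sense base at the position
    partner_base: str | None  # tRNA-sense base at the partner, if any


@dataclass
class CloverleafMap:
    """Per-gene cloverleaf position table.

    Position numbers follow the mitotRNAdb convention for that gene.  They
    need not be contiguous (truncated arms skip numbers) nor unique
    (insertion positions reuse the preceding number and are never paired),
    but every sequence index appears exactly once and the partner relation
    is symmetric over uniquely numbered entries.
    """

    gene: str
    entries: tuple[CloverleafEntry, ...]
    _by_index: dict[int, CloverleafEntry] = field(init=False, repr=False)
    _paired_by_number: dict[int, CloverleafEntry] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.entries = tuple(sorted(self.entries, key=lambda e: e.seq_index))
        by_index: dict[int, CloverleafEntry] = {}
        for e in self.entries:
            if e.element not in ELEMENTS:
                raise CatalogError(f"{self.gene}: unknown element {e.element!r}")
            if e.seq_index in by_index:
                raise CatalogError(f"{self.gene}: duplicate sequence index {e.seq_index}")
            by_index[e.seq_index] = e
        self._by_index = by_index

        numbers: dict[int, list[CloverleafEntry]] = {}
        for e in self.entries:
            numbers.setdefault(e.position_number, []).append(e)
        paired: dict[int, CloverleafEntry] = {}
        for e in self.entries:
            if e.partner is None:
                continue
            if len(numbers[e.position_number]) > 1:
                raise CatalogError(
                    f"{self.gene}: paired position number {e.position_number} is not unique"
                )
            paired[e.position_number] = e
        for num, e in paired.items():
            mate = paired.get(e.partner)
            if mate is None or mate.partner != num:
                raise CatalogError(
                    f"{self.gene}: asymmetric partner table at position {num} "
                    f"(partner {e.partner})"
                )
        self._paired_by_number = paired

    def entry_at_index(self, seq_index: int) -> CloverleafEntry:
        try:
            return self._by_index[seq_index]
        except KeyError:
            raise CatalogError(
                f"{self.gene}: sequence index {seq_index} missing from position table"
            ) from None

    def partner_entry(self, entry: CloverleafEntry) -> CloverleafEntry | None:
        if entry.partner is None:
            return None
        return self._paired_by_number[entry.partner]


@dataclass
class Catalog:
    """The full reference model: 22 genes plus their cloverleaf maps."""

    genes: tuple[TRNAGene, ...]
    maps: tuple[CloverleafMap, ...]

    def __post_init__(self) -> None:
        self._genes_by_name = {g.name: g for g in self.genes}
        self._maps_by_gene = {m.gene: m for m in self.maps}
        for m in self.maps:
            gene = self._genes_by_name.get(m.gene)
            if gene is None:
                raise CatalogError(f"position table for unknown gene {m.gene!r}")
            indices = {e.seq_index for e in m.entries}
            if indices != set(range(1, gene.length + 1)):
                raise CatalogError(
                    f"{m.gene}: position table does not cover sequence indices "
                    f"1..{gene.length} exactly"
                )
        missing = set(self._genes_by_name) - set(self._maps_by_gene)
        if missing:
            raise CatalogError(f"genes without position tables: {sorted(missing)}")
        spans = sorted((g.start, g.end, g.name) for g in self.genes)
        for (s1, e1, n1), (s2, e2, n2) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise CatalogError(f"overlapping genes {n1} and {n2}")

    def gene(self, name: str) -> TRNAGene:
        try:
            return self._genes_by_name[name]
        except KeyError:
            raise CatalogError(f"unknown gene {name!r}") from None

    def map_for(self, name: str) -> CloverleafMap:
        return self._maps_by_gene[self.gene(name).name]

    def locate(self, genomic_pos: int) -> GeneHit:
        if not 1 <= genomic_pos <= MT_GENOME_LENGTH:
            raise ValueError(f"rCRS coordinate {genomic_pos} outside 1..{MT_GENOME_LENGTH}")
        for g in self.genes:
            if g.contains(genomic_pos):
                return GeneHit(gene=g, offset=g.offset_of(genomic_pos))
        raise NoGeneHitError(f"position {genomic_pos} is not inside any mt-tRNA gene")

    def position_info(self, gene_name: str, genomic_pos: int) -> PositionInfo:
        gene = self.gene(gene_name)
        offset = gene.offset_of(genomic_pos)  # raises NoGeneHitError if outside
        cmap = self.map_for(gene_name)
        entry = cmap.entry_at_index(offset)
        mate = cmap.partner_entry(entry)
        return PositionInfo(
            trna_position=entry.position_number,
            element=entry.element,
            partner=entry.partner,
            ref_base=gene.sequence[offset - 1],
            partner_base=gene.sequence[mate.seq_index - 1] if mate else None,
        )


def locate(catalog: Catalog, genomic_pos: int) -> GeneHit:
    """Containing gene and strand-corrected offset for an rCRS coordinate."""
    return catalog.locate(genomic_pos)


def trna_position(catalog: Catalog, gene: str | TRNAGene, genomic_pos: int) -> PositionInfo:
    """mitotRNAdb position number, element, partner and reference bases."""
    name = gene.name if isinstance(gene, TRNAGene) else gene
    return catalog.position_info(name, genomic_pos)


# ---------------------------------------------------------------------------
# Catalog file I/O.  Two record types, tab-separated:
#   gene <name> <start> <end> <strand> <sequence>
#   pos  <gene> <position_number> <seq_index> <element> <partner|.>
# Blank lines and lines starting with '#' are ignored.
# ---------------------------------------------------------------------------


def load_catalog(path: str | Path) -> Catalog:
    """Read and validate a catalog file; every map invariant is checked."""
    path = Path(path)
    genes: list[TRNAGene] = []
    entries: dict[str, list[CloverleafEntry]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            kind = fields[0]
            try:
                if kind == "gene":
                    _, name, start, end, strand, seq = fields
                    genes.append(
                        TRNAGene(name=name, start=int(start), end=int(end), strand=strand,
                                 sequence=seq.upper())
                    )
                elif kind == "pos":
                    _, gname, number, index, element, partner = fields
                    entries.setdefault(gname, []).append(
                        CloverleafEntry(
                            position_number=int(number),
                            seq_index=int(index),
                            element=element,
                            partner=None if partner == "." else int(partner),
                        )
                    )
                else:
                    raise CatalogError(f"unknown record type {kind!r}")
            except (ValueError, CatalogError) as exc:
                raise CatalogError(f"{path.name}:{lineno}: {exc}") from None
    maps = tuple(CloverleafMap(gene=g, entries=tuple(es)) for g, es in entries.items())
    return Catalog(genes=tuple(genes), maps=maps)


def write_catalog(catalog: Catalog, path: str | Path, header: Iterable[str] = ()) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for line in header:
            fh.write(f"# {line}\n")
        for g in catalog.genes:
            fh.write(f"gene\t{g.name}\t{g.start}\t{g.end}\t{g.strand}\t{g.sequence}\n")
        for m in catalog.maps:
            for e in m.entries:
                partner = "." if e.partner is None else str(e.partner)
                fh.write(
                    f"pos\t{m.gene}\t{e.position_number}\t{e.seq_index}\t{e.element}\t{partner}\n"
                )


@lru_cache(maxsize=1)
def default_catalog() -> Catalog:
    """The bundled synthetic reference catalog (see module docstring)."""
    ref = resources.files("mttrnascreen.data").joinpath("mt_trna_catalog.synthetic.tsv")
    with resources.as_file(ref) as p:
        return load_catalog(p)
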