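"""Structural interpretation of mtDNA substitutions in tRNA genes.

A :class:`Variant` is a single substitution in rCRS coordinates.
:func:`annotate_variant` maps it into the cloverleaf: gene, mitotRNAdb
position number, structural element, and the Watson-Crick base-pair effect
at stem positions.  Only A/C/G/T substitutions are modelled; variants are
treated as homoplasmic presence/absence, and insertions/deletions are out
of scope.

Strand convention: variants are stated with rCRS alleles even inside
L-strand genes.  Alleles are complemented to tRNA sense before structural
interpretation; reports echo the original rCRS alleles, and the rendered
pair string uses rCRS-allele space with the 5'-side base first.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from enum import Enum

from .catalog import Catalog, GeneHit, PositionInfo, complement

__all__ = [
    "Variant",
    "PairEffect",
    "StructuralAnnotation",
    "ReferenceMismatchError",
    "WATSON_CRICK",
    "is_watson_crick",
    "basepair_effect",
    "annotate_variant",
    "call_variants",
]

logger = logging.getLogger(__name__)

_LABEL_RE = re.compile(r"^(?:m\.)?(\d+)([ACGT])>([ACGT])$")

#: Watson-Crick partners.  G·T (G·U) wobble is deliberately excluded: the
#: screen treats a C-G -> U·G change as a disrupted pair and T·G -> C-G as a
#: created one.
WATSON_CRICK = {"A": "T", "T": "A", "G": "C", "C": "G"}


def is_watson_crick(a: str, b: str) -> bool:
    if a not in WATSON_CRICK or b not in WATSON_CRICK:
        raise ValueError(f"invalid base pair {a!r}/{b!r}")
    return WATSON_CRICK[a] == b


class PairEffect(str, Enum):
    NONE = "none"
    CREATED = "created"
    DISRUPTED = "disrupted"

    @property
    def arrow(self) -> str:
        return {"none": "", "created": "↑", "disrupted": "↓"}[self.value]


class ReferenceMismatchError(ValueError):
    """The stated reference allele disagrees with the catalog sequence.

    Usually signals a wrong coordinate or an uncomplemented L-strand allele.
    """


@dataclass(frozen=True, order=True)
class Variant:
    """A substitution in 1-based rCRS coordinates, alleles in rCRS terms."""

    position: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        for b in (self.ref, self.alt):
            if b not in "ACGT" or len(b) != 1:
                raise ValueError(f"{self.label}: alleles must be single A/C/G/T bases")
        if self.ref == self.alt:
            raise ValueError(f"{self.label}: ref equals alt")
        if self.position < 1:
            raise ValueError(f"{self.label}: position must be positive")

    @property
    def label(self) -> str:
        return f"m.{self.position}{self.ref}>{self.alt}"

    @property
    def short_label(self) -> str:
        """Table-style label without the ``m.`` prefix, e.g. ``7544C>T``."""
        return f"{self.position}{self.ref}>{self.alt}"

    @classmethod
    def from_label(cls, label: str) -> "Variant":
        m = _LABEL_RE.match(label.strip())
        if not m:
            raise ValueError(f"cannot parse variant label {label!r}")
        return cls(position=int(m.group(1)), ref=m.group(2), alt=m.group(3))


@dataclass(frozen=True)
class StructuralAnnotation:
    variant: Variant
    gene: str
    trna_position: int
    element: str
    pair_effect: PairEffect
    pair_string: str  # e.g. "C-G", empty when unpaired
    partner: int | None

    @property
    def wc_annotation(self) -> str:
        """Rendered pairing column, e.g. ``C-G↓``; empty when no effect."""
        if self.pair_effect is PairEffect.NONE:
            return ""
        return f"{self.pair_string}{self.pair_effect.arrow}"


def basepair_effect(ref_base: str, alt_base: str, partner_base: str | None) -> PairEffect:
    """Effect of a substitution on the Watson-Crick status of a pair.

    ``disrupted`` when the reference pair is Watson-Crick and the mutant is
    not; ``created`` for the reverse; ``none`` otherwise or when there is no
    partner.  Bases are compared in a common (tRNA-sense) strand frame.
    """
    if partner_base is None:
        for b in (ref_base, alt_base):
            if b not in WATSON_CRICK:
                raise ValueError(f"invalid base {b!r}")
        return PairEffect.NONE
    before = is_watson_crick(ref_base, partner_base)
    after = is_watson_crick(alt_base, partner_base)
    if before and not after:
        return PairEffect.DISRUPTED
    if after and not before:
        return PairEffect.CREATED
    return PairEffect.NONE


def _render_pair(
    hit: GeneHit, info: PositionInfo, variant: Variant, effect: PairEffect
) -> str:
    """Render the involved pair in rCRS-allele space, 5'-side base first.

    Disrupted pairs show the reference alleles; created pairs show the
    mutant allele at the variant position (the pair that comes into being),
    matching how screening reports conventionally print the arrow column.
    """
    if info.partner is None:
        return ""
    strand = hit.gene.strand
    own_sense = variant.alt if effect is PairEffect.CREATED else variant.ref
    if strand == "L":
        own_sense = complement(own_sense)
    partner_sense = info.partner_base
    # back to rCRS-allele space for display
    own = own_sense if strand == "H" else complement(own_sense)
    mate = partner_sense if strand == "H" else complement(partner_sense)
    if info.trna_position <= info.partner:  # variant position is the 5' side
        return f"{own}-{mate}"
    return f"{mate}-{own}"


def annotate_variant(catalog: Catalog, variant: Variant) -> StructuralAnnotation:
    """Full structural annotation of a substitution; deterministic.

    Raises :class:`~mttrnascreen.catalog.NoGeneHitError` outside tRNA genes
    and :class:`ReferenceMismatchError` when the stated reference allele does
    not match the catalog after strand correction.
    """
    hit = catalog.locate(variant.position)
    info = catalog.position_info(hit.gene.name, variant.position)
    sense_ref = variant.ref if hit.gene.strand == "H" else complement(variant.ref)
    sense_alt = variant.alt if hit.gene.strand == "H" else complement(variant.alt)
    if sense_ref != info.ref_base:
        expected = info.ref_base if hit.gene.strand == "H" else complement(info.ref_base)
        raise ReferenceMismatchError(
            f"{variant.label}: reference allele {variant.ref} does not match catalog "
            f"base {expected} at rCRS {variant.position} in {hit.gene.name} "
            f"({hit.gene.strand} strand)"
        )
    effect = basepair_effect(sense_ref, sense_alt, info.partner_base)
    return StructuralAnnotation(
        variant=variant,
        gene=hit.gene.name,
        trna_position=info.trna_position,
        element=info.element,
        pair_effect=effect,
        pair_string=_render_pair(hit, info, variant, effect),
        partner=info.partner,
    )


def call_variants(
    ref_segment: str, sample_segment: str, segment_start: int
) -> list[Variant]:
    """Positional mismatch scan of two equal-length, gap-free segments.

    Not an aligner: base calling and alignment are assumed upstream.  Returns
    one :class:`Variant` per mismatching position, in coordinate order.
    Non-ACGT sample bases are treated as missing and skipped (count logged).
    """
    if len(ref_segment) != len(sample_segment):
        raise ValueError(
            f"segment length mismatch: {len(ref_segment)} vs {len(sample_segment)}"
        )
    ref_segment = ref_segment.upper()
    sample_segment = sample_segment.upper()
    out: list[Variant] = []
    skipped = 0
    for i, (r, s) in enumerate(zip(ref_segment, sample_segment)):
        if r not in "ACGT" or s not in "ACGT":
            skipped += 1
            continue
        if r != s:
            out.append(Variant(position=segment_start + i, ref=r, alt=s))
    if skipped:
        logger.info("call_variants: skipped %d non-ACGT position(s)", skipped)
    return out
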