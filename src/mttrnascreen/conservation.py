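"""Conservation index (CI) of tRNA positions from multi-species alignments.

The CI of a column is the percentage of non-human species whose aligned
base matches the human base.  Species gapped at the column are excluded
from the denominator, so the effective depth varies per position.  A CI of
at least 75% flags the position as functionally important.

Alignments are consumed as gapped rows (aligned FASTA or Stockholm via
Biopython); U and T are treated as the same base and comparison is
case-insensitive.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from Bio import AlignIO

__all__ = [
    "CI_THRESHOLD",
    "SpeciesAlignment",
    "ConservationResult",
    "UndefinedCIError",
    "read_alignment",
    "column_for_position",
    "conservation_index",
    "is_functionally_important",
]

#: Functional-importance threshold, in percent.  Inclusive: a CI of exactly
#: 75.0 counts as functionally important.
CI_THRESHOLD = 75.0

GAP_CHARS = frozenset("-.")


def _norm(seq: str) -> str:
    return seq.upper().replace("U", "T")


class UndefinedCIError(ValueError):
    """Every non-human row is gapped at the queried column."""


@dataclass(frozen=True)
class ConservationResult:
    ci_percent: float
    n_match: int
    n_compared: int

    @property
    def functionally_important(self) -> bool:
        return is_functionally_important(self.ci_percent)


@dataclass
class SpeciesAlignment:
    """Gapped alignment rows keyed by species name, with a designated human row."""

    rows: dict[str, str]
    human: str = "Homo sapiens"

    def __post_init__(self) -> None:
        if self.human not in self.rows:
            raise ValueError(f"human row {self.human!r} missing from alignment")
        self.rows = {name: _norm(seq) for name, seq in self.rows.items()}
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) != 1:
            raise ValueError(f"rows have unequal lengths: {sorted(lengths)}")

    @property
    def length(self) -> int:
        return len(self.rows[self.human])

    @property
    def human_row(self) -> str:
        return self.rows[self.human]

    def subset(self, species: list[str]) -> "SpeciesAlignment":
        """Restrict to a caller-supplied species set (human always kept)."""
        keep = {self.human, *species}
        missing = keep - set(self.rows)
        if missing:
            raise ValueError(f"species not in alignment: {sorted(missing)}")
        return SpeciesAlignment(
            rows={k: v for k, v in self.rows.items() if k in keep}, human=self.human
        )


def read_alignment(
    path: str | Path, fmt: str = "fasta", human: str = "Homo sapiens"
) -> SpeciesAlignment:
    """Load an aligned FASTA or Stockholm file into a :class:`SpeciesAlignment`."""
    aln = AlignIO.read(str(path), fmt)
    rows: dict[str, str] = {}
    for rec in aln:
        name = rec.description if fmt == "fasta" else rec.id
        if name in rows:
            raise ValueError(f"duplicate species {name!r} in {path}")
        rows[name] = str(rec.seq)
    return SpeciesAlignment(rows=rows, human=human)


def column_for_position(alignment: SpeciesAlignment, human_sequence_index: int) -> int:
    """1-based alignment column holding the index-th non-gap human base."""
    if human_sequence_index < 1:
        raise IndexError(f"sequence index {human_sequence_index} must be >= 1")
    seen = 0
    for col, ch in enumerate(alignment.human_row, 1):
        if ch not in GAP_CHARS:
            seen += 1
            if seen == human_sequence_index:
                return col
    raise IndexError(
        f"sequence index {human_sequence_index} beyond ungapped human length {seen}"
    )


def conservation_index(alignment: SpeciesAlignment, column: int) -> ConservationResult:
    """CI of a 1-based alignment column.

    The human row must be ungapped at the column; rows gapped there are
    excluded from the denominator.
    """
    if not 1 <= column <= alignment.length:
        raise IndexError(f"column {column} outside 1..{alignment.length}")
    human_base = alignment.human_row[column - 1]
    if human_base in GAP_CHARS:
        raise ValueError(f"human row is gapped at column {column}")
    n_match = n_compared = 0
    for name, seq in alignment.rows.items():
        if name == alignment.human:
            continue
        base = seq[column - 1]
        if base in GAP_CHARS:
            continue
        n_compared += 1
        if base == human_base:
            n_match += 1
    if n_compared == 0:
        raise UndefinedCIError(f"all non-human rows gapped at column {column}")
    return ConservationResult(
        ci_percent=100.0 * n_match / n_compared, n_match=n_match, n_compared=n_compared
    )


def is_functionally_important(ci_percent: float) -> bool:
    """Inclusive threshold: true iff CI >= 75%."""
    if not 0.0 <= ci_percent <= 100.0:
        raise ValueError(f"CI {ci_percent} outside 0..100")
    return ci_percent >= CI_THRESHOLD
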