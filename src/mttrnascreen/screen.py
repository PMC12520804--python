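"""Pathogenicity screen for mt-tRNA variants.

A variant is a *pathogenic candidate* when it (1) is carried by fewer than
1% of controls, (2) sits at a position with conservation index >= 75%, and
(3) alters a Watson-Crick base pair (the structural criterion this screen
computes).  A fourth line of evidence - impaired mitochondrial function in
cell models - is wet-lab input recorded separately as
``functional_evidence``; an untested variant can still be a candidate,
since functional work follows the screen.  Variants carried only by
controls are classified benign polymorphisms; everything else is uncertain.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum
from typing import Iterable, Sequence

from .conservation import is_functionally_important
from .stats import CarrierCounts
from .variants import PairEffect, StructuralAnnotation

__all__ = [
    "MAX_CONTROL_FREQ",
    "Classification",
    "FunctionalEvidence",
    "ScreenRecord",
    "ScreenSummary",
    "screen_variant",
    "summarize",
]

#: Criterion 1 bound: candidate variants appear in strictly less than 1% of
#: the control group.
MAX_CONTROL_FREQ = 0.01


class Classification(str, Enum):
    CANDIDATE_PATHOGENIC = "candidate_pathogenic"
    BENIGN_POLYMORPHISM = "benign_polymorphism"
    UNCERTAIN = "uncertain"


class FunctionalEvidence(str, Enum):
    SUPPORTED = "supported"
    REFUTED = "refuted"
    UNTESTED = "untested"


@dataclass(frozen=True)
class ScreenRecord:
    """One screening-report row: annotation + CI + counts + test outcome."""

    annotation: StructuralAnnotation
    ci_percent: float | None
    counts: CarrierCounts
    p: float | None
    functional_evidence: FunctionalEvidence
    classification: Classification
    previously_reported: bool

    @property
    def control_freq_percent(self) -> float:
        return self.counts.control_percent

    @property
    def significant(self) -> bool:
        return self.p is not None and self.p < 0.05


@dataclass(frozen=True)
class ScreenSummary:
    n_variants: int
    n_genes: int
    n_control_only: int
    n_ci_ge_75: int
    n_wc_altering: int
    n_significant: int


def _classify(
    annotation: StructuralAnnotation,
    ci_percent: float | None,
    counts: CarrierCounts,
) -> Classification:
    rare_in_controls = counts.control_frequency < MAX_CONTROL_FREQ
    conserved = ci_percent is not None and is_functionally_important(ci_percent)
    structural = annotation.pair_effect is not PairEffect.NONE
    if counts.a == 0 and counts.c > 0:
        return Classification.BENIGN_POLYMORPHISM
    if rare_in_controls and conserved and structural:
        return Classification.CANDIDATE_PATHOGENIC
    return Classification.UNCERTAIN


def screen_variant(
    annotation: StructuralAnnotation,
    counts: CarrierCounts,
    ci_percent: float | None = None,
    p: float | None = None,
    functional_evidence: FunctionalEvidence | str = FunctionalEvidence.UNTESTED,
    previously_reported: bool = False,
) -> ScreenRecord:
    """Apply the screening criteria to one annotated variant.

    A missing CI fails the conservation criterion closed.  Functional
    evidence is never computed here (it is cell-model data) and does not
    gate candidacy; it is carried through for reporting.
    """
    if counts.a + counts.c == 0 and p is not None:
        raise ValueError(
            f"{annotation.variant.label}: p-value supplied for a table with no carriers"
        )
    return ScreenRecord(
        annotation=annotation,
        ci_percent=ci_percent,
        counts=counts,
        p=p,
        functional_evidence=FunctionalEvidence(functional_evidence),
        classification=_classify(annotation, ci_percent, counts),
        previously_reported=previously_reported,
    )


def with_functional_evidence(
    record: ScreenRecord, evidence: FunctionalEvidence | str
) -> ScreenRecord:
    """Attach wet-lab functional evidence to an existing record."""
    return replace(record, functional_evidence=FunctionalEvidence(evidence))


def summarize(records: Sequence[ScreenRecord] | Iterable[ScreenRecord]) -> ScreenSummary:
    """Deterministic summary counts over a set of screen records."""
    records = list(records)
    genes = {r.annotation.gene for r in records}
    return ScreenSummary(
        n_variants=len(records),
        n_genes=len(genes),
        n_control_only=sum(1 for r in records if r.counts.a == 0 and r.counts.c > 0),
        n_ci_ge_75=sum(
            1
            for r in records
            if r.ci_percent is not None and is_functionally_important(r.ci_percent)
        ),
        n_wc_altering=sum(
            1 for r in records if r.annotation.pair_effect is not PairEffect.NONE
        ),
        n_significant=sum(1 for r in records if r.significant),
    )
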