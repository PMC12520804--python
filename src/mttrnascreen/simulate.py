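"""Synthetic cohorts, alignments and mutated sequences.

Generates data with the statistical structure the screening pipeline
assumes, so every stage is testable without external downloads.  Defaults
emulate the study population: 302 cases and 589 controls, clinical
covariates drawn as independent zero-truncated Gaussians at the published
group means/SDs, carrier status per variant as group-specific Bernoulli
draws (or planted exactly for golden tests), and multi-species alignments
with exact per-column match fractions over 15 non-human species.

What this generator does NOT emulate: realistic mtDNA mutational spectra,
haplogroup backgrounds, covariate correlation structure, or linkage
between variants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import homa_ir
from .variants import Variant

__all__ = [
    "TABLE1_CLINICAL",
    "DEFAULT_N_CASES",
    "DEFAULT_N_CONTROLS",
    "DEFAULT_N_SPECIES",
    "CohortSpec",
    "AlignmentSpec",
    "simulate_cohort",
    "simulate_alignment",
    "mutate_sequence",
    "planted_recovery_rate",
    "null_significant_rate",
]

DEFAULT_N_CASES = 302
DEFAULT_N_CONTROLS = 589
DEFAULT_N_SPECIES = 15

#: Published group-level clinical parameters: covariate -> (case mean,
#: case SD, control mean, control SD).  HOMA-IR is not sampled; it is
#: computed from the simulated insulin and glucose so the formula is
#: exercised downstream.
TABLE1_CLINICAL: dict[str, tuple[float, float, float, float]] = {
    "age": (28.54, 4.79, 26.14, 4.27),          # years
    "bmi": (23.89, 3.21, 19.12, 2.34),          # kg/m^2
    "fsh": (5.27, 1.38, 6.79, 3.11),            # IU/L
    "lh": (11.44, 7.17, 5.91, 3.71),            # IU/L
    "lh_fsh_ratio": (2.12, 1.01, 0.92, 0.69),
    "prl": (20.64, 7.85, 13.19, 11.15),         # ug/L
    "dheas": (9.22, 3.01, 6.55, 2.61),          # umol/L
    "tt": (0.75, 0.30, 0.51, 0.17),             # ng/mL
    "fins": (16.74, 5.30, 6.21, 1.55),          # mU/L
    "fpg": (5.22, 1.51, 5.19, 0.49),            # mmol/L
    "ck": (55.2, 3.55, 22.5, 0.69),             # U/L
    "lactate": (3.55, 0.88, 1.01, 0.06),        # mmol/L
}


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a simulated two-group cohort.

    ``variant_freqs`` maps a variant label to (case carrier frequency,
    control carrier frequency).  In ``exact`` mode the carrier count per
    group is planted as round(freq * n) deterministically (carriers chosen
    by the seeded RNG); ``bernoulli`` mode draws per-subject carrier status.
    """

    n_cases: int = DEFAULT_N_CASES
    n_controls: int = DEFAULT_N_CONTROLS
    variant_freqs: dict[str, tuple[float, float]] = field(default_factory=dict)
    clinical_params: dict[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(TABLE1_CLINICAL)
    )
    seed: int = 0
    mode: str = "bernoulli"

    def __post_init__(self) -> None:
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("group sizes must be positive")
        if self.mode not in ("bernoulli", "exact"):
            raise ValueError(f"unknown planting mode {self.mode!r}")
        for label, (fa, fc) in self.variant_freqs.items():
            if not (0.0 <= fa <= 1.0 and 0.0 <= fc <= 1.0):
                raise ValueError(f"{label}: frequencies must lie in [0, 1]")
        for cov, (m1, s1, m0, s0) in self.clinical_params.items():
            if s1 <= 0 or s0 <= 0:
                raise ValueError(f"{cov}: SDs must be positive")


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, n: int
) -> np.ndarray:
    """Gaussian truncated at zero from below (physiological values > 0)."""
    a = (0.0 - mean) / sd
    dist = sps.truncnorm(a, np.inf, loc=mean, scale=sd)
    return dist.rvs(size=n, random_state=rng)


def simulate_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate genotype and clinical tables for a two-group cohort.

    Returns ``(genotypes, clinical)``.  ``genotypes`` is long format
    (``subject_id``, ``group``, ``variant``), one row per carried variant;
    ``clinical`` has one row per subject with the covariate columns of
    :data:`TABLE1_CLINICAL` plus computed ``homa_ir`` and ``ir_flag``.
    Identical seeds give identical output.
    """
    rng = np.random.default_rng(spec.seed)
    subjects = [(f"case{i + 1:04d}", "case") for i in range(spec.n_cases)] + [
        (f"ctrl{i + 1:04d}", "control") for i in range(spec.n_controls)
    ]

    geno_rows: list[tuple[str, str, str]] = []
    for label, (f_case, f_ctrl) in spec.variant_freqs.items():
        for group, freq, n, prefix in (
            ("case", f_case, spec.n_cases, "case"),
            ("control", f_ctrl, spec.n_controls, "ctrl"),
        ):
            if spec.mode == "exact":
                k = int(round(freq * n))
                carriers = rng.choice(n, size=k, replace=False)
            else:
                carriers = np.flatnonzero(rng.random(n) < freq)
            geno_rows.extend(
                (f"{prefix}{int(i) + 1:04d}", group, label) for i in sorted(carriers)
            )
    genotypes = pd.DataFrame(geno_rows, columns=["subject_id", "group", "variant"])

    clinical = pd.DataFrame(
        {"subject_id": [s for s, _ in subjects], "group": [g for _, g in subjects]}
    )
    n1, n0 = spec.n_cases, spec.n_controls
    for cov, (m1, s1, m0, s0) in spec.clinical_params.items():
        vals = np.concatenate(
            [_truncated_normal(rng, m1, s1, n1), _truncated_normal(rng, m0, s0, n0)]
        )
        clinical[cov] = vals
    if "fins" in clinical.columns and "fpg" in clinical.columns:
        scored = [homa_ir(i, g) for i, g in zip(clinical["fins"], clinical["fpg"])]
        clinical["homa_ir"] = [s for s, _ in scored]
        clinical["ir_flag"] = [f for _, f in scored]
    return genotypes, clinical


@dataclass(frozen=True)
class AlignmentSpec:
    """Parameters of a synthetic multi-species alignment.

    ``match_fractions`` gives the target fraction of non-human species
    matching the human base at each column; each must be representable
    exactly as k/n_species.
    """

    n_species: int = DEFAULT_N_SPECIES
    match_fractions: tuple[float, ...] = ()
    seed: int = 0

    @property
    def length(self) -> int:
        return len(self.match_fractions)


def simulate_alignment(spec: AlignmentSpec, human: str = "Homo sapiens"):
    """Build an alignment with exact per-column match counts.

    At each column exactly ``round(f * n_species)`` seeded-random species
    carry the human base and the rest carry a different base; a fraction
    not representable as k/n_species raises ``ValueError``.  Returns a
    :class:`~mttrnascreen.conservation.SpeciesAlignment`.
    """
    from .conservation import SpeciesAlignment

    rng = np.random.default_rng(spec.seed)
    bases = np.array(list("ACGT"))
    names = [human] + [f"species{i + 1:02d}" for i in range(spec.n_species)]
    cols: dict[str, list[str]] = {n: [] for n in names}
    for j, f in enumerate(spec.match_fractions):
        k = f * spec.n_species
        if abs(k - round(k)) > 1e-9:
            raise ValueError(
                f"column {j + 1}: match fraction {f} is not a multiple of "
                f"1/{spec.n_species}"
            )
        k = int(round(k))
        human_base = rng.choice(bases)
        others = [b for b in "ACGT" if b != human_base]
        matching = set(rng.choice(spec.n_species, size=k, replace=False))
        cols[human].append(str(human_base))
        for i in range(spec.n_species):
            name = names[i + 1]
            if i in matching:
                cols[name].append(str(human_base))
            else:
                cols[name].append(str(rng.choice(others)))
    return SpeciesAlignment(rows={n: "".join(c) for n, c in cols.items()}, human=human)


def mutate_sequence(
    ref_segment: str, variants: list[Variant], segment_start: int
) -> str:
    """Substitute alt alleles into a reference segment (inverse of
    :func:`~mttrnascreen.variants.call_variants`).

    Every variant must fall inside the segment, match the reference allele,
    and occupy a distinct position.
    """
    seq = list(ref_segment.upper())
    seen: set[int] = set()
    for v in variants:
        idx = v.position - segment_start
        if not 0 <= idx < len(seq):
            raise ValueError(f"{v.label}: outside segment starting at {segment_start}")
        if v.position in seen:
            raise ValueError(f"duplicate position {v.position}")
        seen.add(v.position)
        if seq[idx] != v.ref:
            raise ValueError(
                f"{v.label}: reference allele {v.ref} does not match segment base "
                f"{seq[idx]}"
            )
        seq[idx] = v.alt
    return "".join(seq)


# ---------------------------------------------------------------------------
# Desk-scale calibration experiments: power to recover a planted
# case-enriched variant, and the null false-positive rate of the screen's
# association test at rare-variant carrier counts.
# ---------------------------------------------------------------------------


def _replicate_pvalues(
    spec: CohortSpec, labels: list[str]
) -> dict[str, float]:
    from .stats import DegenerateTableError, pearson_chi2, tabulate

    geno, _ = simulate_cohort(spec)
    out = {}
    for label in labels:
        counts = tabulate(geno, label, spec.n_cases, spec.n_controls)
        try:
            out[label] = pearson_chi2(counts).p
        except DegenerateTableError:
            out[label] = 1.0  # no carriers anywhere: nothing to detect
    return out


def study_background_freqs() -> dict[str, tuple[float, float]]:
    """Null background emulating the study: every screened variant except
    the case-associated one, at its observed pooled carrier frequency in
    both groups (42 variants, frequencies ~0.0011-0.0067)."""
    from .io import load_study_table

    out: dict[str, tuple[float, float]] = {}
    for _, row in load_study_table().iterrows():
        if row["mutation"] == "7544C>T":
            continue
        total = int(row["case_carriers"]) + int(row["control_carriers"])
        f = total / (DEFAULT_N_CASES + DEFAULT_N_CONTROLS)
        out[row["variant"].label] = (f, f)
    return out


def planted_recovery_rate(
    n_replicates: int = 200,
    planted_freqs: tuple[float, float] = (0.02, 0.001),
    background: dict[str, tuple[float, float]] | None = None,
    n_cases: int = DEFAULT_N_CASES,
    n_controls: int = DEFAULT_N_CONTROLS,
    seed: int = 0,
) -> float:
    """Fraction of simulated cohorts where the planted case-enriched variant
    is the top association hit (smallest p; a tie for smallest counts, since
    sparse carrier tables often coincide exactly).

    Each replicate simulates carrier status for the planted variant at the
    given case/control frequencies plus a null background (default:
    :func:`study_background_freqs`), runs the full tabulate-and-test path,
    and ranks variants by p.
    """
    planted = "m.7544C>T"
    background = study_background_freqs() if background is None else background
    nulls = list(background)
    freqs = {planted: planted_freqs} | background
    hits = 0
    for rep in range(n_replicates):
        spec = CohortSpec(
            n_cases=n_cases, n_controls=n_controls, variant_freqs=freqs,
            clinical_params={}, seed=seed + rep,
        )
        ps = _replicate_pvalues(spec, [planted] + nulls)
        if ps[planted] <= min(ps[x] for x in nulls):
            hits += 1
    return hits / n_replicates


def null_significant_rate(
    n_replicates: int = 200,
    freq: float = 0.005,
    n_cases: int = DEFAULT_N_CASES,
    n_controls: int = DEFAULT_N_CONTROLS,
    seed: int = 0,
) -> float:
    """Fraction of null replicates (equal carrier frequency in both groups)
    whose association test reports p < 0.05.

    At very small carrier counts the uncorrected Pearson chi-square is known
    to stray from its nominal level, so this empirical rate is a calibration
    check rather than an exact 5%.
    """
    label = "m.1000A>G"
    significant = 0
    for rep in range(n_replicates):
        spec = CohortSpec(
            n_cases=n_cases, n_controls=n_controls,
            variant_freqs={label: (freq, freq)}, clinical_params={},
            seed=seed + rep,
        )
        if _replicate_pvalues(spec, [label])[label] < 0.05:
            significant += 1
    return significant / n_replicates
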