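"""Case-control tabulation and the study's statistics.

Association between a variant and case status is tested on the 2x2 carrier
table with the uncorrected Pearson chi-square (df=1).  No continuity
correction is applied and Fisher's exact test is not the default: on the
sparse tables typical of rare mtDNA variants (e.g. 2/302 carriers vs 0/589)
only the uncorrected statistic reproduces the reference results, Yates and
Fisher being far more conservative.  Fisher is available behind a flag and
is clearly a deviation from the default convention.  No multiple-testing
adjustment is applied by default; an optional Bonferroni column can be
requested.

Also included: pooled-variance Student's t for clinical covariates (Welch
optional), HOMA-IR and BMI, and the 2^-ddCt qPCR fold change.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "HOMA_IR_THRESHOLD",
    "CarrierCounts",
    "TestResult",
    "DegenerateTableError",
    "tabulate",
    "pearson_chi2",
    "fisher_exact",
    "carrier_percent",
    "students_t",
    "homa_ir",
    "bmi",
    "ddct_fold_change",
    "bonferroni",
]

#: HOMA-IR score at or above which a subject is called insulin resistant.
HOMA_IR_THRESHOLD = 2.69


class DegenerateTableError(ValueError):
    """The 2x2 table has a zero margin; the chi-square test is undefined."""


@dataclass(frozen=True)
class CarrierCounts:
    """2x2 case-control carrier table.

    ``a``: case carriers, ``b``: case non-carriers, ``c``: control carriers,
    ``d``: control non-carriers.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError(f"negative cell in {self}")

    @property
    def n_cases(self) -> int:
        return self.a + self.b

    @property
    def n_controls(self) -> int:
        return self.c + self.d

    @property
    def total(self) -> int:
        return self.n_cases + self.n_controls

    @property
    def case_percent(self) -> float:
        return carrier_percent(self.a, self.n_cases)

    @property
    def control_percent(self) -> float:
        return carrier_percent(self.c, self.n_controls)

    @property
    def control_frequency(self) -> float:
        """Carrier fraction among controls (0..1)."""
        if self.n_controls == 0:
            raise ValueError("no controls")
        return self.c / self.n_controls


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p: float
    df: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"p-value {self.p} outside [0, 1]")


def tabulate(
    genotypes: pd.DataFrame,
    variant_label: str,
    n_cases: int,
    n_controls: int,
) -> CarrierCounts:
    """Count carriers of one variant from a long-format genotype table.

    ``genotypes`` has columns ``subject_id``, ``group`` (``case``/``control``)
    and ``variant`` (canonical ``m.<pos><ref>><alt>`` labels); one row per
    carried variant per subject.  A subject carries the variant iff listed
    with it.  Group sizes are supplied by the caller because non-carriers do
    not appear in the table.
    """
    required = {"subject_id", "group", "variant"}
    missing = required - set(genotypes.columns)
    if missing:
        raise ValueError(f"genotype table missing columns {sorted(missing)}")
    bad_groups = set(genotypes["group"].unique()) - {"case", "control"}
    if bad_groups:
        raise ValueError(f"unknown group label(s) {sorted(bad_groups)}")
    rows = genotypes[genotypes["variant"] == variant_label]
    if rows.duplicated(subset=["subject_id"]).any():
        dup = rows[rows.duplicated(subset=["subject_id"])]["subject_id"].iloc[0]
        raise ValueError(f"subject {dup!r} listed twice for {variant_label}")
    a = int((rows["group"] == "case").sum())
    c = int((rows["group"] == "control").sum())
    if a > n_cases or c > n_controls:
        raise ValueError(
            f"{variant_label}: carrier counts ({a} cases, {c} controls) exceed "
            f"group sizes ({n_cases}/{n_controls})"
        )
    return CarrierCounts(a=a, b=n_cases - a, c=c, d=n_controls - c)


def pearson_chi2(counts: CarrierCounts) -> TestResult:
    """Uncorrected Pearson chi-square on a 2x2 table, df=1, two-sided p.

    chi2 = n (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)).  Raises
    :class:`DegenerateTableError` when any margin is zero (in particular
    when there is no carrier at all).
    """
    a, b, c, d = counts.a, counts.b, counts.c, counts.d
    margins = (a + b, c + d, a + c, b + d)
    if 0 in margins:
        raise DegenerateTableError(f"zero margin in table {counts}")
    n = counts.total
    chi2 = n * (a * d - b * c) ** 2 / float(np.prod([float(m) for m in margins]))
    p = float(sps.chi2.sf(chi2, df=1))
    return TestResult(statistic=float(chi2), p=p, df=1)


def fisher_exact(counts: CarrierCounts) -> TestResult:
    """Two-sided Fisher exact test (optional small-count alternative).

    Deviates from the default screening convention, which is the
    uncorrected Pearson chi-square; the odds ratio is returned as the
    statistic and df is reported as 0.
    """
    odds, p = sps.fisher_exact([[counts.a, counts.b], [counts.c, counts.d]])
    return TestResult(statistic=float(odds), p=float(p), df=0)


def carrier_percent(k: int, n: int) -> float:
    """Carrier percentage 100k/n, rounded to 2 decimals for display."""
    if n <= 0:
        raise ValueError("group size must be positive")
    if not 0 <= k <= n:
        raise ValueError(f"carrier count {k} outside 0..{n}")
    return round(100.0 * k / n, 2)


def students_t(
    values_a: Sequence[float], values_b: Sequence[float], welch: bool = False
) -> TestResult:
    """Two-sample t test, pooled variance by default (Welch optional)."""
    x, y = np.asarray(values_a, float), np.asarray(values_b, float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 observations")
    t, p = sps.ttest_ind(x, y, equal_var=not welch)
    if welch:
        df = _welch_df(x, y)
    else:
        df = len(x) + len(y) - 2
    return TestResult(statistic=float(t), p=float(p), df=int(round(df)))


def _welch_df(x: np.ndarray, y: np.ndarray) -> float:
    vx, vy = x.var(ddof=1) / len(x), y.var(ddof=1) / len(y)
    return (vx + vy) ** 2 / (vx**2 / (len(x) - 1) + vy**2 / (len(y) - 1))


def homa_ir(fins: float, fpg: float) -> tuple[float, bool]:
    """HOMA-IR score and insulin-resistance flag.

    score = fasting insulin (mU/L) x fasting glucose (mmol/L) / 22.5; the
    flag is true at or above 2.69 (inclusive).
    """
    if fins <= 0 or fpg <= 0:
        raise ValueError("insulin and glucose must be positive")
    score = fins * fpg / 22.5
    return score, score >= HOMA_IR_THRESHOLD


def bmi(weight_kg: float, height_m: float) -> float:
    """Body mass index, kg/m^2."""
    if weight_kg <= 0 or height_m <= 0:
        raise ValueError("weight and height must be positive")
    return weight_kg / height_m**2


def ddct_fold_change(
    ct_target_test: float,
    ct_ref_test: float,
    ct_target_ctrl: float,
    ct_ref_ctrl: float,
) -> float:
    """Relative expression fold change by the 2^-ddCt method."""
    cts = (ct_target_test, ct_ref_test, ct_target_ctrl, ct_ref_ctrl)
    if not all(np.isfinite(cts)):
        raise ValueError("Ct values must be finite")
    ddct = (ct_target_test - ct_ref_test) - (ct_target_ctrl - ct_ref_ctrl)
    return float(2.0 ** (-ddct))


def bonferroni(p_values: Iterable[float]) -> list[float]:
    """Bonferroni-adjusted p-values (optional report column; the default
    screening report applies no multiple-testing correction)."""
    ps = list(p_values)
    m = len(ps)
    return [min(1.0, p * m) for p in ps]
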