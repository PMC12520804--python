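"""Association statistics and clinical formulas."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from mttrnascreen.stats import (
    CarrierCounts,
    DegenerateTableError,
    bmi,
    bonferroni,
    carrier_percent,
    ddct_fold_change,
    fisher_exact,
    homa_ir,
    pearson_chi2,
    students_t,
    tabulate,
)


def chi2_oracle(a, b, c, d):
    """Independent oracle: sum (O-E)^2/E over expected counts."""
    obs = np.array([[a, b], [c, d]], float)
    n = obs.sum()
    exp = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / n
    return ((obs - exp) ** 2 / exp).sum()


class TestPearsonChi2:
    @pytest.mark.parametrize(
        "table,p_printed",
        [
            ((2, 300, 0, 589), 0.048),
            ((1, 301, 0, 589), 0.16),
            ((4, 298, 2, 587), 0.09),
            ((3, 299, 1, 588), 0.08),
        ],
    )
    def test_reference_tables(self, table, p_printed):
        """Uncorrected Pearson reproduces the published p on sparse carrier
        tables (Yates or Fisher would not: e.g. 0.22 / 0.12 for the first)."""
        res = pearson_chi2(CarrierCounts(*table))
        decimals = 3 if p_printed < 0.05 else 2
        assert round(res.p, decimals) == p_printed
        assert res.df == 1

    def test_equal_proportions(self):
        res = pearson_chi2(CarrierCounts(1, 99, 1, 99))
        assert res.statistic == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_agrees_with_oracle_small_sweep(self):
        """Formula route equals the sum (O-E)^2/E oracle to 1e-12."""
        for a, b, c, d in itertools.product(range(0, 8), repeat=4):
            counts = CarrierCounts(a, b, c, d)
            if 0 in (a + b, c + d, a + c, b + d):
                continue
            assert pearson_chi2(counts).statistic == pytest.approx(
                chi2_oracle(a, b, c, d), abs=1e-12
            )

    def test_group_swap_invariance(self):
        a = pearson_chi2(CarrierCounts(2, 300, 0, 589))
        b = pearson_chi2(CarrierCounts(0, 589, 2, 300))
        assert a.statistic == pytest.approx(b.statistic)
        assert a.p == pytest.approx(b.p)

    def test_degenerate_tables_rejected(self):
        with pytest.raises(DegenerateTableError):
            pearson_chi2(CarrierCounts(0, 302, 0, 589))  # no carriers

    def test_fisher_option_differs_on_sparse_tables(self):
        """The Fisher alternative is deliberately not the default: it is far
        more conservative on the sparse reference table."""
        counts = CarrierCounts(2, 300, 0, 589)
        assert fisher_exact(counts).p > 0.10 > pearson_chi2(counts).p


class TestTabulate:
    def _geno(self):
        rows = [
            ("case0001", "case", "m.7544C>T"),
            ("case0002", "case", "m.7544C>T"),
            ("ctrl0001", "control", "m.634T>C"),
        ]
        return pd.DataFrame(rows, columns=["subject_id", "group", "variant"])

    def test_counts_partition_groups(self):
        counts = tabulate(self._geno(), "m.7544C>T", 302, 589)
        assert (counts.a, counts.b, counts.c, counts.d) == (2, 300, 0, 589)
        counts = tabulate(self._geno(), "m.634T>C", 302, 589)
        assert (counts.a, counts.c) == (0, 1)

    def test_absent_variant_and_empty_table(self):
        counts = tabulate(self._geno(), "m.3302A>G", 302, 589)
        assert (counts.a, counts.b, counts.c, counts.d) == (0, 302, 0, 589)
        empty = pd.DataFrame(columns=["subject_id", "group", "variant"])
        counts = tabulate(empty, "m.7544C>T", 10, 20)
        assert (counts.a, counts.c) == (0, 0)

    def test_duplicate_subject_rejected(self):
        geno = pd.concat([self._geno(), self._geno().iloc[[0]]])
        with pytest.raises(ValueError, match="twice"):
            tabulate(geno, "m.7544C>T", 302, 589)

    def test_unknown_group_rejected(self):
        geno = self._geno()
        geno.loc[0, "group"] = "patient"
        with pytest.raises(ValueError, match="group"):
            tabulate(geno, "m.7544C>T", 302, 589)


class TestCarrierPercent:
    @pytest.mark.parametrize("k,n,expected", [(2, 302, 0.66), (4, 302, 1.32), (0, 589, 0.0)])
    def test_examples(self, k, n, expected):
        assert carrier_percent(k, n) == expected

    def test_zero_group_rejected(self):
        with pytest.raises(ValueError):
            carrier_percent(0, 0)


class TestStudentsT:
    def test_identical_groups(self):
        res = students_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_pooled_closed_form(self):
        # pooled sd = 1, se = sqrt(2/3): t = -3 / 0.8165 = -3.674, df = 4
        res = students_t([1, 2, 3], [4, 5, 6])
        assert res.statistic == pytest.approx(-3.674, abs=1e-3)
        assert res.p == pytest.approx(0.0213, abs=1e-3)
        assert res.df == 4

    def test_scale_invariance(self):
        a, b = [1.0, 2.0, 5.0], [4.0, 4.5, 6.0]
        t1 = students_t(a, b).statistic
        t2 = students_t([10 * x for x in a], [10 * x for x in b]).statistic
        assert t1 == pytest.approx(t2)

    def test_welch_option(self):
        a, b = [1.0, 2.0, 3.0, 4.0], [10.0, 30.0, 50.0]
        welch = students_t(a, b, welch=True)
        expected = sps.ttest_ind(a, b, equal_var=False)
        assert welch.statistic == pytest.approx(expected.statistic)
        assert welch.p == pytest.approx(expected.pvalue)

    def test_tiny_group_rejected(self):
        with pytest.raises(ValueError):
            students_t([1.0], [1.0, 2.0])


class TestClinicalFormulas:
    def test_homa_ir_identity_and_group_means(self):
        score, flag = homa_ir(22.5, 1.0)
        assert (score, flag) == (pytest.approx(1.0), False)
        # product of published group means; not the published mean score,
        # since the mean of products differs from the product of means
        score, flag = homa_ir(16.74, 5.22)
        assert round(score, 2) == 3.88
        assert flag is True

    def test_homa_ir_threshold_inclusive(self):
        score, flag = homa_ir(2.69 * 22.5 / 5.0, 5.0)
        assert score == pytest.approx(2.69)
        assert flag is True

    def test_homa_ir_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            homa_ir(0.0, 5.0)

    def test_bmi(self):
        assert bmi(60, 1.6) == pytest.approx(23.44, abs=5e-3)
        assert bmi(70, 1.0) == pytest.approx(70.0)
        assert bmi(70, 2.0) == pytest.approx(bmi(70, 1.0) / 4)

    @pytest.mark.parametrize(
        "cts,fold",
        [
            ((20, 20, 20, 20), 1.0),
            ((21, 20, 20, 20), 0.5),   # ddCt = +1
            ((18, 20, 20, 20), 4.0),   # ddCt = -2
        ],
    )
    def test_ddct(self, cts, fold):
        assert ddct_fold_change(*cts) == pytest.approx(fold)

    def test_ddct_rejects_non_finite(self):
        with pytest.raises(ValueError):
            ddct_fold_change(float("nan"), 20, 20, 20)

    def test_bonferroni(self):
        assert bonferroni([0.01, 0.5]) == [0.02, 1.0]
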