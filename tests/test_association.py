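"""Contingency tests, ANOVA and region-phenotype association."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from cytocn.association import (
    anova_oneway,
    chi_square,
    region_state_matrix,
    run_association,
)
from cytocn.recurrence import Region
from cytocn.segmentation import SegState
from conftest import make_segment
from oracles import permutation_anova_p

MB = 1_000_000


class TestChiSquare:
    def test_diagnosis_by_cn_state(self):
        """2x3 adenocarcinoma vs mucinous table, no correction."""
        res = chi_square([[0, 13, 41], [1, 0, 7]])
        assert res.df == 2
        assert res.p_value == pytest.approx(0.0123, rel=0.05)

    def test_2x2_with_continuity_correction(self):
        res = chi_square([[13, 54], [11, 8]], correction="yates")
        assert res.df == 1
        assert res.p_value == pytest.approx(0.003, rel=0.15)

    def test_all_zero_column_dropped_before_df(self):
        """Stage table whose Amplification column is empty: df from the 3x2."""
        res = chi_square([[0, 5, 6], [0, 0, 16], [0, 1, 34]])
        assert res.observed.shape == (3, 2)
        assert res.df == 2
        assert res.p_value == pytest.approx(0.000053, rel=0.05)

    def test_proportional_rows_give_unit_p(self):
        res = chi_square([[10, 20], [5, 10]])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_degenerate_table_untestable(self):
        res = chi_square([[0, 0], [3, 4]])
        assert not res.testable
        assert res.p_value is None

    def test_permutation_invariance(self, rng):
        t = rng.integers(0, 30, (3, 3))
        base = chi_square(t).p_value
        assert chi_square(t[::-1, :]).p_value == pytest.approx(base)
        assert chi_square(t[:, ::-1]).p_value == pytest.approx(base)
        assert chi_square(t.T).p_value == pytest.approx(base)

    def test_yates_requires_2x2(self):
        with pytest.raises(ValueError):
            chi_square([[1, 2, 3], [4, 5, 6]], correction="yates")

    def test_negative_or_fractional_counts_rejected(self):
        with pytest.raises(ValueError):
            chi_square([[1, -2], [3, 4]])
        with pytest.raises(ValueError):
            chi_square([[1.5, 2], [3, 4]])


def groups_with_moments(n, mean, sd, rng):
    """Sample with exact mean and exact (ddof=1) standard deviation."""
    x = rng.normal(size=n)
    x = (x - x.mean()) / x.std(ddof=1)
    return mean + sd * x


class TestAnova:
    def test_tumor_cell_fraction_difference(self, rng):
        """MSI 74.6 (SD 6.24, n=24) vs MSS 71.2 (SD 6.48, n=62) -> p ~ 0.03."""
        vals = np.concatenate([
            groups_with_moments(24, 74.6, 6.24, rng),
            groups_with_moments(62, 71.2, 6.48, rng),
        ])
        groups = np.array(["MSI"] * 24 + ["MSS"] * 62)
        f, p = anova_oneway(vals, groups)
        assert p == pytest.approx(0.03, abs=0.01)

    def test_two_group_f_equals_squared_pooled_t(self, rng):
        from scipy import stats
        a = rng.normal(0, 1, 20)
        b = rng.normal(0.5, 1, 25)
        f, p = anova_oneway(np.concatenate([a, b]), np.array(["a"] * 20 + ["b"] * 25))
        t = stats.ttest_ind(a, b, equal_var=True)
        assert f == pytest.approx(t.statistic**2)
        assert p == pytest.approx(t.pvalue)

    def test_identical_groups(self):
        vals = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        f, p = anova_oneway(vals, np.array(["a"] * 3 + ["b"] * 3))
        assert f == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_large_shift_agrees_with_permutation_oracle(self, rng):
        """3 groups, one shifted by 10 sd: parametric p < 1e-6 and no
        permutation statistic ever reaches the observed one."""
        vals = np.concatenate([rng.normal(0, 1, 10), rng.normal(0, 1, 10),
                               rng.normal(10, 1, 10)])
        groups = np.repeat(["a", "b", "c"], 10)
        _, p = anova_oneway(vals, groups)
        assert p < 1e-6
        p_perm = permutation_anova_p(vals, groups, 2000, rng)
        assert p_perm == pytest.approx(1 / 2001)

    def test_degenerate_constant_groups(self):
        f, p = anova_oneway(np.array([1.0, 1.0, 2.0, 2.0]), np.array(["a", "a", "b", "b"]))
        assert np.isinf(f) and p == 0.0

    def test_too_few_groups_rejected(self):
        with pytest.raises(ValueError):
            anova_oneway(np.array([1.0, 2.0]), np.array(["a", "a"]))


def region(chrom=1, start=10 * MB, end=20 * MB, event="AMP"):
    return Region(chrom, start, end, event, (), 0, 0)


class TestStateMatrix:
    def test_full_span_and_no_overlap(self):
        reg = region()
        segs = {
            "S_amp": [make_segment("S_amp", 1, 10 * MB + 1, 20 * MB, SegState.AMPLIFIED)],
            "S_none": [make_segment("S_none", 2, MB, 2 * MB, SegState.AMPLIFIED)],
            "S_missing": None,
        }
        m = region_state_matrix([reg], segs)
        col = m.iloc[:, 0]
        assert col["S_amp"] == "Amplification"
        assert col["S_none"] == "Unchanged"
        assert pd.isna(col["S_missing"])

    def test_half_coverage_rule(self):
        reg = region()
        covers_49 = make_segment("a", 1, 10 * MB + 1, int(14.9 * MB), SegState.DELETED)
        covers_50 = make_segment("b", 1, 10 * MB + 1, 15 * MB, SegState.DELETED)
        m = region_state_matrix([reg], {"a": [covers_49], "b": [covers_50]})
        assert m.iloc[:, 0]["a"] == "Unchanged"
        assert m.iloc[:, 0]["b"] == "Deletion"

    def test_planted_state_proportions(self, rng):
        """30% amplified / 70% unchanged cohort: column sums match the plant."""
        reg = region()
        segs = {}
        for i in range(40):
            name = f"S{i:02d}"
            if i < 12:
                segs[name] = [make_segment(name, 1, 10 * MB + 1, 20 * MB, SegState.AMPLIFIED)]
            else:
                segs[name] = []
        m = region_state_matrix([reg], segs)
        counts = m.iloc[:, 0].value_counts()
        assert counts.get("Amplification", 0) == 12
        assert counts.get("Unchanged", 0) == 28


class TestRunAssociation:
    @staticmethod
    def planted_cohort(rng, n=80, odds=(0.6, 0.05)):
        reg = region()
        segs, rows = {}, []
        sides = rng.choice(["left", "right"], size=n, p=[0.6, 0.4])
        for i, side in enumerate(sides):
            name = f"S{i:03d}"
            p_carry = odds[0] if side == "left" else odds[1]
            if rng.random() < p_carry:
                segs[name] = [make_segment(name, 1, 10 * MB + 1, 20 * MB, SegState.AMPLIFIED)]
            else:
                segs[name] = []
            rows.append({"sample_id": name, "location": side, "msi": "MSS"})
        return reg, segs, pd.DataFrame(rows)

    def test_planted_association_detected(self, rng):
        reg, segs, pheno = self.planted_cohort(rng)
        m = region_state_matrix([reg], segs)
        res = run_association([reg], m, pheno, phenotype_cols=["location"])
        assert len(res) == 1
        assert res.iloc[0]["p"] < 0.01

    def test_planted_association_power(self, rng):
        """Strong planted effect detected at p<0.01 in >=80% of replicates."""
        hits = 0
        for _ in range(100):
            reg, segs, pheno = self.planted_cohort(rng)
            m = region_state_matrix([reg], segs)
            res = run_association([reg], m, pheno, phenotype_cols=["location"])
            hits += bool(res.iloc[0]["testable"] and res.iloc[0]["p"] < 0.01)
        assert hits >= 80

    def test_single_sample_stratum_untestable(self):
        reg = region()
        segs = {"S0": [make_segment("S0", 1, 10 * MB + 1, 20 * MB, SegState.AMPLIFIED)]}
        pheno = pd.DataFrame({"sample_id": ["S0"], "location": ["left"], "msi": ["MSS"]})
        m = region_state_matrix([reg], segs)
        res = run_association([reg], m, pheno, phenotype_cols=["location"])
        assert not res.iloc[0]["testable"]

    def test_msi_stratification_splits_cohort(self, rng):
        reg, segs, pheno = self.planted_cohort(rng, n=40)
        pheno.loc[:19, "msi"] = "MSI"
        m = region_state_matrix([reg], segs)
        res = run_association([reg], m, pheno, phenotype_cols=["location"])
        assert set(res["stratum"]) == {"MSI", "MSS"}
        assert (res["n"] <= 20).all()
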