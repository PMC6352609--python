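"""Questionnaire scoring, grouping rules, and the inferential battery."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mibci.containers import SubjectRecord
from mibci.errors import ValidationError
from mibci.stats import (
    bh_adjust,
    categorize_kv,
    glass_delta,
    mann_whitney_u,
    pearson_r,
    run_correlation_table,
    run_group_comparisons,
    score_miq,
    shapiro_wilk,
    spearman_rho,
    split_manual,
    split_perf,
    welch_t,
)


def _record(answers, freq_manual=3, sid="S01"):
    return SubjectRecord(
        subject_id=sid,
        miq_answers=answers,
        age=25.0,
        gender="M",
        education_years=3.0,
        freq_manual=freq_manual,
        freq_sport=2,
        freq_music=1,
        freq_craft=0,
        freq_gaming=4,
    )


class TestScoring:
    def test_score_bounds(self):
        assert score_miq(_record([7] * 14)).kmi_score == pytest.approx(100.0)
        assert score_miq(_record([1] * 14)).kmi_score == pytest.approx(0.0)
        assert score_miq(_record([1] * 14)).vmi_score == pytest.approx(0.0)

    def test_alternating_answers_exact_arithmetic(self):
        answers = [1, 7, 1, 7, 1, 7, 1] + [4] * 7
        expected = (25 / 7 - 1) / 6 * 100  # mean 25/7 rescaled
        assert score_miq(_record(answers)).kmi_score == pytest.approx(expected)
        assert expected == pytest.approx(42.857142857, abs=1e-6)

    def test_subset_scores_use_declared_items(self):
        answers = [7, 1, 7, 1, 7, 1, 7] + [4] * 7
        s = score_miq(_record(answers), subsets={"hand": (2, 4, 6), "arm": (1, 3, 5, 7)})
        assert s.kmi_hand_score == pytest.approx(0.0)  # items 2,4,6 are all 1
        assert s.kmi_arm_score == pytest.approx(100.0)

    @given(st.lists(st.integers(1, 7), min_size=14, max_size=14))
    @settings(max_examples=50, deadline=None)
    def test_rescaling_is_affine_and_order_preserving(self, answers):
        s = score_miq(_record(answers))
        k = answers[:7]
        assert 0.0 <= s.kmi_score <= 100.0
        assert s.kmi_score == pytest.approx((np.mean(k) - 1) / 6 * 100)


class TestGrouping:
    @pytest.mark.parametrize(
        "k,v,expected",
        [(70, 70, "K+V+"), (69.99, 100, "K-V+"), (100, 69.99, "K+V-"), (0, 0, "K-V-")],
    )
    def test_kv_boundary_at_70(self, k, v, expected):
        assert categorize_kv(k, v) == expected

    def test_perf_split_strictly_above_mean(self):
        assert split_perf([0.6, 0.8]) == ["Perf-", "Perf+"]
        assert split_perf([0.7, 0.7, 0.7]) == ["Perf-"] * 3  # none strictly above

    def test_perf_split_partitions_and_orders_means(self):
        r = np.random.default_rng(0)
        acc = r.uniform(0.5, 1.0, 35)
        groups = np.array(split_perf(acc))
        assert len(groups) == 35
        assert acc[groups == "Perf+"].mean() > acc[groups == "Perf-"].mean()

    @pytest.mark.parametrize(
        "level,expected",
        [("daily", "Manual+"), ("weekly", "Manual+"), ("monthly", "Manual-"),
         ("annually", "Manual-"), ("never", "Manual-"), (5, "Manual+"), (3, "Manual-")],
    )
    def test_manual_split(self, level, expected):
        assert split_manual(level) == expected

    def test_manual_split_unknown_level(self):
        with pytest.raises(ValidationError, match="unknown frequency level"):
            split_manual("fortnightly")


class TestCorrelations:
    def test_perfect_linear_relation(self):
        x = np.arange(10.0)
        res = pearson_r(x, 2 * x + 1)
        assert res.estimate == pytest.approx(1.0)
        assert res.p_value < 1e-6

    def test_spearman_detects_monotone_nonlinearity(self):
        x = np.linspace(0.1, 3.0, 12)
        y = np.exp(3 * x)
        assert spearman_rho(x, y).estimate == pytest.approx(1.0)
        assert pearson_r(x, y).estimate < 1.0

    def test_pearson_matches_direct_formula_oracle(self):
        r = np.random.default_rng(1)
        x, y = r.standard_normal(25), r.standard_normal(25)
        oracle = ((x - x.mean()) * (y - y.mean())).sum() / (
            np.sqrt(((x - x.mean()) ** 2).sum()) * np.sqrt(((y - y.mean()) ** 2).sum())
        )
        assert pearson_r(x, y).estimate == pytest.approx(oracle, abs=1e-12)

    def test_constant_variable_rejected(self):
        with pytest.raises(ValidationError, match="constant"):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestGroupTests:
    def test_welch_identical_groups(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        res = welch_t(a, a)
        assert res.estimate == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_welch_matches_formula_oracle(self):
        r = np.random.default_rng(2)
        a = r.normal(0, 1, 5)
        b = r.normal(1, 10, 50)
        va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
        t_oracle = (a.mean() - b.mean()) / np.sqrt(va + vb)
        df_oracle = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
        from scipy import stats as spst

        p_oracle = 2 * spst.t.sf(abs(t_oracle), df_oracle)
        res = welch_t(a, b)
        assert res.estimate == pytest.approx(t_oracle, abs=1e-10)
        assert res.p_value == pytest.approx(p_oracle, abs=1e-10)

    def test_mann_whitney_exact_matches_exhaustive_enumeration(self):
        a, b = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        res = mann_whitney_u(a, b)
        assert res.estimate == 0.0  # complete separation
        # exhaustive permutation oracle over C(6,3)=20 group assignments
        pooled = a + b
        observed = res.estimate

        def ustat(group_a):
            group_b = [v for v in pooled if v not in group_a]
            return sum(1 for x in group_a for y in group_b if x > y)

        us = [ustat(c) for c in itertools.combinations(pooled, 3)]
        u_obs = min(observed, len(a) * len(b) - observed)
        p_exact = np.mean([min(u, 9 - u) <= u_obs for u in us])
        assert res.p_value == pytest.approx(p_exact)
        assert p_exact == pytest.approx(0.1)

    def test_shapiro_wilk_flags_heavy_skew(self):
        r = np.random.default_rng(3)
        assert shapiro_wilk(r.normal(size=50)).p_value > 0.01
        assert shapiro_wilk(r.exponential(size=50) ** 3).p_value < 0.01


class TestGlassDelta:
    def test_equal_means_zero(self):
        assert glass_delta([1.0, 2, 3], [2.0, 2, 2]).estimate == pytest.approx(0.0)

    def test_direct_arithmetic(self):
        # means 10 vs 12, control SD 4 -> delta 0.5
        control = np.array([6.0, 14.0, 6.0, 14.0])  # mean 10, sd ~4.62
        control = 10 + (control - 10) * (4 / control.std(ddof=1))
        res = glass_delta(control, [12.0, 12.0])
        assert res.estimate == pytest.approx(0.5)

    def test_control_selection_symmetric_in_argument_order(self):
        r = np.random.default_rng(4)
        big, small = r.normal(0, 2, 20), r.normal(1, 5, 5)
        assert glass_delta(big, small).estimate == pytest.approx(
            glass_delta(small, big).estimate
        )

    def test_zero_control_sd_rejected(self):
        with pytest.raises(ValidationError, match="zero standard deviation"):
            glass_delta([2.0, 2.0, 2.0], [1.0, 3.0])


class TestBenjaminiHochberg:
    def test_nothing_rejected_when_all_p_one(self):
        rejected, thr = bh_adjust(np.ones(6), q=0.20)
        assert not rejected.any()
        assert thr == 0.0

    def test_step_up_example(self):
        rejected, thr = bh_adjust([0.01, 0.02, 0.5, 0.9], q=0.20)
        assert list(rejected) == [True, True, False, False]
        assert thr == pytest.approx(2 * 0.20 / 4)

    def test_single_p_value(self):
        assert bh_adjust([0.04], q=0.05)[0][0]
        assert not bh_adjust([0.06], q=0.05)[0][0]

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        r = np.random.default_rng(5)
        for _ in range(20):
            p = r.uniform(size=r.integers(2, 30))
            ours, _ = bh_adjust(p, q=0.2)
            theirs = multipletests(p, alpha=0.2, method="fdr_bh")[0]
            assert np.array_equal(ours, theirs)

    def test_matches_independent_step_up_oracle(self):
        def oracle(p, q):
            p = np.asarray(p)
            m = len(p)
            idx = np.argsort(p)
            k = 0
            for rank, i in enumerate(idx, start=1):
                if p[i] <= rank * q / m:
                    k = rank
            return p <= (k * q / m if k else 0.0)

        r = np.random.default_rng(6)
        for _ in range(50):
            p = r.uniform(size=10) ** 2
            assert np.array_equal(bh_adjust(p, 0.2)[0], oracle(p, 0.2))

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20))
    @settings(max_examples=100, deadline=None)
    def test_rejections_monotone_in_q(self, pvals):
        lo, _ = bh_adjust(pvals, q=0.05)
        hi, _ = bh_adjust(pvals, q=0.20)
        assert np.all(hi[lo])  # anything rejected at q=0.05 stays rejected at 0.20


class TestReports:
    def _cohort(self, n=20, seed=0):
        r = np.random.default_rng(seed)
        records = [
            _record(list(r.integers(1, 8, size=14)), freq_manual=int(r.integers(0, 6)),
                    sid=f"S{i:02d}")
            for i in range(n)
        ]
        acc = r.uniform(0.5, 1.0, n)
        return records, acc

    def test_duplicated_factor_yields_identical_correlations(self):
        records, acc = self._cohort()
        for rec in records:
            rec.freq_craft = rec.freq_manual  # duplicate column
        report = run_correlation_table(records, {"tslr": acc})
        t = report.table.set_index("variable")
        assert t.loc["freq_craft", "pearson_r"] == pytest.approx(
            t.loc["freq_manual", "pearson_r"], abs=1e-12
        )

    def test_families_and_thresholds_reported(self):
        records, acc = self._cohort()
        report = run_correlation_table(records, {"mdrm": acc, "tslr": acc})
        assert set(report.thresholds) == {"miq_scores", "personal_factors"}
        fam = report.table.loc[report.table["family"] == "miq_scores"]
        assert len(fam) == 4  # 2 methods x {KMI, VMI}

    def test_wide_score_table_has_one_row_per_classifier(self):
        from mibci.stats import score_table

        records, acc = self._cohort()
        report = run_correlation_table(records, {"mdrm": acc, "tslr": acc})
        wide = score_table(report, ("kmi_score", "vmi_score"))
        assert set(wide.index) == {"mdrm", "tslr"}
        assert list(wide.columns) == [
            "kmi_score_r", "kmi_score_p", "vmi_score_r", "vmi_score_p"
        ]

    def test_group_comparisons_cover_declared_contrasts(self):
        records, acc = self._cohort(n=30, seed=1)
        df = run_group_comparisons(records, acc)
        assert {"welch_t", "mann_whitney_u", "glass_delta"} <= set(df["test"])
        assert any("Perf+" in c for c in df["comparison"])
        assert any("Manual+" in c for c in df["comparison"])
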