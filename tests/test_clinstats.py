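"""Summary-statistic inference, FDR, gated correlation, outliers, and the
demographic report."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import fnirskit as fk
from fnirskit.clinstats import (
    SummaryGroup,
    anova_from_summary,
    chi_square_test,
    correlate_gated,
    correlation_pvalue,
    demographic_table,
    exclude_outliers,
    fdr_bh,
    t_from_summary,
)


def _moment_matched(mean, sd, n, seed=0):
    """Raw sample with exactly the requested mean and sd (ddof=1)."""
    z = np.random.default_rng(seed).normal(size=n)
    z = (z - z.mean()) / z.std(ddof=1)
    return mean + sd * z


class TestSummaryAnova:
    def test_identical_groups_give_f_zero(self):
        g = SummaryGroup(5.0, 1.0, 10)
        res = anova_from_summary([g, g, g])
        assert res.F == 0.0
        assert res.p == pytest.approx(1.0)

    @pytest.mark.parametrize("k,ns", [(2, (8, 12)), (3, (5, 9, 14)), (5, (4, 6, 8, 10, 12))])
    def test_summary_equals_raw_anova_on_moment_matched_data(self, k, ns):
        rng = np.random.default_rng(k)
        means = rng.uniform(-1, 1, k)
        sds = rng.uniform(0.5, 2.0, k)
        samples = [_moment_matched(m, s, n, seed=i)
                   for i, (m, s, n) in enumerate(zip(means, sds, ns))]
        res = anova_from_summary(
            [SummaryGroup(m, s, n) for m, s, n in zip(means, sds, ns)]
        )
        raw = stats.f_oneway(*samples)
        assert res.F == pytest.approx(raw.statistic, abs=1e-9)
        assert res.p == pytest.approx(raw.pvalue, abs=1e-9)

    def test_zero_variance_everywhere_is_an_error(self):
        with pytest.raises(ValueError):
            anova_from_summary([SummaryGroup(1, 0, 5), SummaryGroup(2, 0, 5)])


class TestSummaryT:
    def test_identical_summaries_give_t_zero(self):
        g = SummaryGroup(3.0, 1.0, 10)
        t, p, df = t_from_summary(g, g)
        assert t == 0.0
        assert df == 18

    def test_pooled_matches_raw_ttest_on_moment_matched_samples(self):
        a = _moment_matched(10.08, 4.77, 20, seed=1)
        b = _moment_matched(12.20, 3.98, 20, seed=2)
        t, p, _ = t_from_summary(
            SummaryGroup(10.08, 4.77, 20), SummaryGroup(12.20, 3.98, 20)
        )
        raw = stats.ttest_ind(a, b)
        assert t == pytest.approx(raw.statistic, abs=1e-9)
        assert p == pytest.approx(raw.pvalue, abs=1e-9)

    def test_welch_matches_scipy(self):
        a = _moment_matched(0.0, 1.0, 12, seed=3)
        b = _moment_matched(1.0, 2.5, 30, seed=4)
        t, p, _ = t_from_summary(
            SummaryGroup(0.0, 1.0, 12), SummaryGroup(1.0, 2.5, 30), pooled=False
        )
        raw = stats.ttest_ind(a, b, equal_var=False)
        assert t == pytest.approx(raw.statistic, abs=1e-9)
        assert p == pytest.approx(raw.pvalue, abs=1e-9)


class TestChiSquare:
    def test_proportional_table_gives_zero(self):
        chi2, p, df = chi_square_test(np.array([[10, 20], [5, 10]]))
        assert chi2 == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_2x2(self):
        chi2, p, df = chi_square_test(np.array([[10, 10], [20, 0]]))
        assert chi2 == pytest.approx(13.3333, abs=1e-3)
        assert df == 1
        sp = stats.chi2_contingency(np.array([[10, 10], [20, 0]]), correction=False)
        assert chi2 == pytest.approx(sp.statistic, rel=1e-12)

    def test_zero_column_is_rejected(self):
        with pytest.raises(ValueError):
            chi_square_test(np.array([[3, 0], [5, 0]]))


class TestFDR:
    def test_single_p_passes_through(self):
        q, rej = fdr_bh([0.03])
        assert q[0] == pytest.approx(0.03)
        assert rej[0]

    def test_equal_ps_stay_equal(self):
        q, _ = fdr_bh([0.2, 0.2, 0.2])
        np.testing.assert_allclose(q, 0.2)

    def test_matches_brute_force_step_up(self):
        p = np.array([0.01, 0.02, 0.03, 0.20])
        q, rej = fdr_bh(p, alpha=0.05)
        m = len(p)
        # exhaustive rank loop
        order = np.argsort(p)
        expected = np.empty(m)
        for rank, idx in enumerate(order, start=1):
            candidates = [p[j] * m / (np.searchsorted(p[order], p[j]) + 1)
                          for j in order[rank - 1:]]
            expected[idx] = min(min(candidates), 1.0)
        np.testing.assert_allclose(q, expected, atol=1e-12)

    def test_matches_statsmodels_and_is_monotone(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(8)
        p = rng.uniform(size=200)
        q, rej = fdr_bh(p, alpha=0.05)
        sm_rej, sm_q, *_ = multipletests(p, alpha=0.05, method="fdr_bh")
        np.testing.assert_allclose(q, sm_q, atol=1e-12)
        np.testing.assert_array_equal(rej, sm_rej)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_rejections_superset_of_bonferroni(self):
        rng = np.random.default_rng(9)
        p = np.concatenate([rng.uniform(0, 0.001, 5), rng.uniform(size=95)])
        q, rej = fdr_bh(p, alpha=0.05)
        bonf = p < 0.05 / p.size
        assert np.all(rej[bonf])

    def test_out_of_range_p_is_rejected(self):
        with pytest.raises(ValueError):
            fdr_bh([0.5, 1.2])


class TestCorrelation:
    def test_p_from_r_formula_matches_scipy_pearson(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=30)
        y = 0.5 * x + rng.normal(size=30)
        r, p = stats.pearsonr(x, y)
        assert correlation_pvalue(r, 30) == pytest.approx(p, rel=1e-9)

    def test_perfectly_linear_data_gives_r_one(self):
        x = np.arange(10, dtype=float)
        res = correlate_gated(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)
        assert res.p == pytest.approx(0.0, abs=1e-12)

    def test_skewed_data_falls_back_to_spearman(self):
        rng = np.random.default_rng(11)
        x = rng.exponential(size=100) ** 3
        y = x + rng.exponential(size=100) ** 3
        res = correlate_gated(x, y)
        assert res.method == "spearman"

    def test_normal_data_uses_pearson(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=100)
        y = 0.3 * x + rng.normal(size=100)
        assert correlate_gated(x, y).method == "pearson"

    def test_zero_variance_is_rejected(self):
        with pytest.raises(ValueError):
            correlate_gated(np.ones(10), np.arange(10.0))


class TestOutliers:
    def test_clean_data_is_identity(self):
        rng = np.random.default_rng(13)
        x = rng.normal(size=40)
        y = 0.5 * x + 0.1 * rng.normal(size=40)
        retained, excluded = exclude_outliers(x, y)
        assert excluded.size == 0
        assert retained.size == 40

    def test_injected_extreme_point_is_excluded(self):
        rng = np.random.default_rng(14)
        x = rng.normal(size=40)
        y = 0.5 * x + 0.1 * rng.normal(size=40)
        y[7] += 10 * y.std()
        retained, excluded = exclude_outliers(x, y)
        assert list(excluded) == [7]

    def test_iqr_rule_available(self):
        x = np.concatenate([np.random.default_rng(15).normal(size=30), [50.0]])
        y = np.concatenate([np.random.default_rng(16).normal(size=30), [0.0]])
        retained, excluded = exclude_outliers(x, y, rule="iqr")
        assert 30 in excluded

    def test_refuses_to_drop_majority(self):
        rng = np.random.default_rng(17)
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        # an absurdly tight threshold would flag nearly every point
        with pytest.raises(ValueError):
            exclude_outliers(x, y, rule="studentized", z_max=0.01)


class TestDemographicTable:
    def test_pattern_of_significance_on_calibrated_cohort(self, small_cohort):
        """Depression-scale rows separate the groups; cognition does not."""
        spec, truth, clinical, _ = small_cohort
        study_spec = fk.CohortSpec(n_per_group=30, seed=31)
        from fnirskit.synth import simulate_clinical

        rng = np.random.default_rng(31)
        ids = {g: [f"{g}-{i}" for i in range(30)] for g in fk.GROUPS}
        table = simulate_clinical(study_spec, rng, ids)
        report = demographic_table(table)
        rows = report.set_index("variable")
        assert rows.loc["HAMD24", "p"] < 0.01
        assert rows.loc["SDSS", "p"] < 0.01
        assert rows.loc["MOCA", "p"] > 0.05
        assert rows.loc["t2dm_duration", "test"] == "t"
        assert rows.loc["sex", "test"] == "chi2"

    def test_single_group_report_has_no_tests(self):
        df = pd.DataFrame(
            {"subject_id": ["a", "b", "c"], "group": "HEALTHY",
             "age": [60.0, 65.0, 70.0]}
        )
        report = demographic_table(df)
        assert (report["test"] == "none").all()

    def test_statistics_match_hand_built_fixture(self):
        rows = []
        for g, (m, s) in zip(fk.GROUPS, [(22.9, 2.67), (3.25, 2.43), (3.75, 1.45)]):
            vals = _moment_matched(m, s, 20, seed=hash(g) % 100)
            for i, v in enumerate(vals):
                rows.append({"subject_id": f"{g}{i}", "group": g, "HAMD24": v})
        report = demographic_table(pd.DataFrame(rows))
        expected = anova_from_summary(
            [SummaryGroup(22.9, 2.67, 20), SummaryGroup(3.25, 2.43, 20),
             SummaryGroup(3.75, 1.45, 20)]
        )
        assert report.iloc[0]["statistic"] == pytest.approx(expected.F, rel=1e-9)
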