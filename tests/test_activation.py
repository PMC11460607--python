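"""Design construction, GLM estimation, and channel-level group inference."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import fnirskit as fk
from fnirskit.activation import (
    build_design,
    canonical_hrf,
    channel_anova,
    fit_glm,
    group_one_sample_t,
    one_sample_t,
    roi_summary,
    task_regressor,
)
from fnirskit._groupcompare import anova_oneway
from fnirskit.clinstats import SummaryGroup, anova_from_summary


class TestDesign:
    def test_default_design_shape_and_peak_delay(self, paradigm):
        d = build_design(paradigm)
        assert d.matrix.shape == (750, 3)
        assert d.columns == ("task", "intercept", "drift")
        task = d.matrix[:, 0]
        assert np.all(task[:150] == 0)  # zero before the first block onset
        # HRF delay: the regressor peaks several seconds after task onset
        assert np.argmax(task) > 150 + 5 * paradigm.fs

    def test_unit_impulse_hrf_reproduces_the_boxcar(self, paradigm):
        reg = task_regressor(paradigm, hrf=np.array([1.0]))
        box = np.zeros(750)
        for on in paradigm.block_onsets_samples:
            box[on : on + 75] = 1.0
        np.testing.assert_allclose(reg, box, atol=1e-12)

    def test_design_is_full_rank_with_and_without_blocks(self, paradigm):
        for per_block in (False, True):
            d = build_design(paradigm, per_block=per_block)
            assert np.linalg.matrix_rank(d.matrix) == d.matrix.shape[1]

    def test_hrf_peaks_near_6_s_and_undershoots(self):
        t = np.arange(0, 32, 0.2)
        h = canonical_hrf(t)
        assert t[np.argmax(h)] == pytest.approx(6.0, abs=1.0)
        assert h.min() < 0  # undershoot present
        assert h.max() == pytest.approx(1.0)


class TestGLM:
    def test_noiseless_regression_recovers_coefficients(self, paradigm):
        d = build_design(paradigm)
        y = d.matrix @ np.array([2.0, 1.0, 0.0])
        fit = fit_glm(y, d)
        assert fit.beta_task == pytest.approx(2.0, abs=1e-10)

    def test_pure_noise_betas_average_to_zero(self, paradigm):
        d = build_design(paradigm)
        rng = np.random.default_rng(0)
        y = rng.normal(size=(1000, 750))
        betas = fit_glm(y, d).beta_task
        se = betas.std(ddof=1) / np.sqrt(1000)
        assert abs(betas.mean()) < 3 * se

    def test_prewhitening_leaves_noiseless_fit_unbiased(self, paradigm):
        d = build_design(paradigm)
        y = d.matrix @ np.array([1.5, 0.5, -0.2])
        fit = fit_glm(y, d, prewhiten=True)
        assert fit.beta_task == pytest.approx(1.5, abs=1e-8)


class TestOneSampleT:
    def test_symmetric_betas_give_t_zero(self):
        t, p = one_sample_t(np.array([-1.0, 1.0]))
        assert t == 0.0
        assert p == pytest.approx(1.0)

    def test_matches_textbook_formula(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        t, p = one_sample_t(x)
        expected = x.mean() / (x.std(ddof=1) / np.sqrt(5))
        assert t == pytest.approx(expected, rel=1e-12)
        sp_t, sp_p = stats.ttest_1samp(x, 0.0)
        assert t == pytest.approx(sp_t, rel=1e-12)
        assert p == pytest.approx(sp_p, rel=1e-12)

    def test_constant_nonzero_betas_raise(self):
        with pytest.raises(ValueError, match="variance"):
            one_sample_t(np.array([2.0, 2.0, 2.0]))


class TestChannelAnova:
    @staticmethod
    def _beta_table(means, n=30, sd=0.1, seed=0, channels=40):
        rng = np.random.default_rng(seed)
        rows = []
        for g, mu in zip(fk.GROUPS, means):
            for s in range(n):
                for ch in range(1, channels + 1):
                    rows.append(
                        {"subject_id": f"{g}-{s}", "group": g, "channel": ch,
                         "beta": rng.normal(mu, sd)}
                    )
        return pd.DataFrame(rows)

    def test_identical_groups_give_f_zero(self):
        bt = self._beta_table([0.5, 0.5, 0.5], n=4, sd=0.0, channels=3)
        # identical values within and between groups: F defined as 0
        omnibus, _ = channel_anova(bt)
        np.testing.assert_allclose(omnibus["F"], 0.0)

    def test_separated_means_all_posthoc_significant(self):
        bt = self._beta_table([0.1, 0.5, 0.9], n=30, sd=0.1, seed=1, channels=5)
        omnibus, posthoc = channel_anova(bt, alpha=0.05)
        assert omnibus["significant"].all()
        assert (posthoc["q"] < 0.05).all()

    def test_f_matches_summary_statistic_route(self):
        """Raw-data ANOVA equals the summary-statistic ANOVA on the same moments."""
        rng = np.random.default_rng(3)
        groups = [rng.normal(m, 1.0, size=12) for m in (0.0, 0.4, 1.0)]
        F_raw, _ = anova_oneway([g[:, None] for g in groups])
        res = anova_from_summary(
            [SummaryGroup(g.mean(), g.std(ddof=1), g.size) for g in groups]
        )
        assert F_raw[0] == pytest.approx(res.F, abs=1e-9)
        sp = stats.f_oneway(*groups)
        assert F_raw[0] == pytest.approx(sp.statistic, rel=1e-9)

    def test_f_invariant_to_shift_and_scale(self):
        rng = np.random.default_rng(6)
        groups = [rng.normal(m, 1.0, size=10)[:, None] for m in (0, 0.5, 1.2)]
        F0, _ = anova_oneway(groups)
        F_shift, _ = anova_oneway([g + 7.0 for g in groups])
        F_scale, _ = anova_oneway([g * 3.0 for g in groups])
        assert F_shift[0] == pytest.approx(F0[0], rel=1e-9)
        assert F_scale[0] == pytest.approx(F0[0], rel=1e-9)

    def test_missing_group_is_rejected(self):
        bt = self._beta_table([0.1, 0.5, 0.9], n=5, channels=2)
        with pytest.raises(ValueError, match="missing group"):
            channel_anova(bt[bt.group != "T2DM"])


class TestRoiSummary:
    def test_single_and_two_channel_rois(self, layout):
        df = pd.DataFrame(
            {"group": ["HEALTHY"] * 40, "channel": range(1, 41),
             "t": np.arange(40, dtype=float)}
        )
        out = roi_summary(df, layout)
        roi_of = layout.roi_map()
        for _, row in out.iterrows():
            chans = [ch for ch, roi in roi_of.items() if roi == row["roi"]]
            expected = df.loc[df.channel.isin(chans), "t"].mean()
            assert row["mean_t"] == pytest.approx(expected)

    def test_group_one_sample_t_table_layout(self, small_cohort, layout):
        *_, cohort = small_cohort
        tt = group_one_sample_t(cohort.beta_table)
        assert len(tt) == 3 * 40
        assert set(tt.group) == set(fk.GROUPS)
        out = roi_summary(tt, layout)
        assert len(out) == 3 * 10
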