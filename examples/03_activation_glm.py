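"""Channel-wise GLM activation analysis on a synthetic cohort.

Fits the canonical-HRF task regressor to every channel's HbO2 trace,
then runs one-sample t tests per group, ROI summaries, and the
three-group ANOVA with Benjamini-Hochberg correction over 40 channels.
"""

import fnirskit as fk
from fnirskit.activation import roi_summary

layout = fk.default_layout()
paradigm = fk.TaskParadigm()
config = fk.AnalysisConfig()

spec = fk.CohortSpec(n_per_group=15, seed=11)
recordings, truth, _ = fk.simulate_cohort(spec, layout, paradigm, config)
cohort = fk.process_cohort(recordings, layout, paradigm, config)
analysis = fk.analyze_cohort(cohort, alpha=config.fdr_alpha)

bt = cohort.beta_table.copy()
bt["roi"] = bt["channel"].map(layout.roi_map())
print("mean task beta (umol/L) by ROI and group:")
print(bt.groupby(["roi", "group"])["beta"].mean().unstack().round(3))

n_sig = int(analysis.channel_omnibus["significant"].sum())
print(f"\nchannels with significant group differences (q < 0.05): {n_sig} / 40")
print("\nmean t per ROI (healthy group):")
t_h = analysis.channel_t[analysis.channel_t.group == "HEALTHY"]
print(roi_summary(t_h, layout).set_index("roi")["mean_t"].round(2))
print("\nBeta is the peak evoked HbO2 change attributable to the task; the "
      "generator grades it HEALTHY > T2DM > T2DM_MDD in the effect ROIs, "
      "and the ANOVA recovers that separation channel by channel.")
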