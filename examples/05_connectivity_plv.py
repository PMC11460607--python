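"""Phase-locking-value functional connectivity and its group comparison.

PLV in [0, 1] measures phase synchrony of the band-limited HbO2 signals
over the task window; 780 unique channel pairs are compared across groups
with ANOVA + FDR.
"""

import numpy as np

import fnirskit as fk

layout = fk.default_layout()
paradigm = fk.TaskParadigm()
config = fk.AnalysisConfig()

spec = fk.CohortSpec(n_per_group=15, seed=17)
recordings, truth, _ = fk.simulate_cohort(spec, layout, paradigm, config)
cohort = fk.process_cohort(recordings, layout, paradigm, config)

block = list(range(5))  # CH1-5 share an oscillator (weakened in the MDD group)
print("mean within-block PLV (CH1-5) by group:")
for group, stack in cohort.plv_by_group.items():
    sub = stack[:, block][:, :, block]
    iu = np.triu_indices(5, k=1)
    print(f"  {group:9s}: {sub[:, iu[0], iu[1]].mean():.3f}")

comp = fk.pairwise_group_compare(cohort.plv_by_group, alpha=config.fdr_alpha)
sig = comp[comp["significant"]]
within = sig[sig.ch_i.isin([c + 1 for c in block]) & sig.ch_j.isin([c + 1 for c in block])]
print(f"\nsignificant pairs (q < 0.05 over 780): {len(sig)}, "
      f"of which within CH1-5: {len(within)}")
print("\nThe generator couples CH1-5 at strength 0.8 except in the depressed "
      "group (0.4); the pairwise ANOVA localizes exactly that block.")
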