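"""The shuffled-label randomization test: is the classifier better than the
best score a full model search can squeeze out of chance?

Repeats the entire model-selection process with true labels and with
labels permuted before each search, then compares the two score samples
with a two-tailed Welch t-test. On a cohort with a 24 h-only effect the
24 h contrast should be significant and the 1 h contrast should not —
the lag pattern of the published study.
"""

import numpy as np

import eegimpact as ei
from eegimpact.simulate import draw_subject_offsets, generate_block, session_blocks

effect = ei.EffectSpec.late_effect(blink_rate_per_min=0,
                                   saccade_rate_per_min=0, jumps_per_block=0)
config = ei.CohortConfig(n_subjects=10, block_duration_s=15.0, effect=effect,
                         seed=3)

vectors = []
for i, sid in enumerate(config.subject_ids()):
    off = draw_subject_offsets(config, i)
    for lag in ("pre", "post1h", "post24h"):
        blocks = [generate_block(config, sid, s, off)[0]
                  for s in session_blocks(lag)]
        vectors.append(ei.session_features(blocks))

for lag in ("post1h", "post24h"):
    table = ei.assemble_table(vectors, lags=("pre", lag))
    res = ei.randomization_test(table, n_seeds=6, n_trials=4, base_seed=1)
    verdict = "significant" if res.comparison.p < 0.05 else "not significant"
    print(f"pre vs {lag}: mean true {np.mean(res.true_scores):.3f}, "
          f"mean shuffled {np.mean(res.shuffled_scores):.3f} "
          f"(selection optimism pushes even chance above 0.5)")
    print(f"  {res.comparison}  -> {verdict}")
print("expected pattern: no effect at 1 h, clear effect at 24 h — "
      "the randomization baseline absorbs the search's optimism bias")
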