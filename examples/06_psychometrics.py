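"""Psychometric curves and the reward-block shift.

Choice probabilities versus signed contrast, split by which side pays the
larger reward, summarized by a lapse-logistic fit per block type.  The
value-weighted decision rule shifts the curve toward the large-reward
side; the difference of fitted biases quantifies that shift.
"""

import lateraldopa as ld
from lateraldopa import behavior as beh

task, observer = ld.TaskConfig(), ld.ObserverParams()
trials = ld.generate_trials(task, observer, 8000, seed=7)

res = beh.analyze_behavior(trials)
table = res["table"]
print("fraction choosing right at zero contrast:")
zc = table[table.signed_contrast == 0]
for _, row in zc.iterrows():
    print(f"  large reward on {row.large_reward_side}: "
          f"{row.frac_right:.3f}  (n={row.n_trials})")

for side, fit in res["fits"].items():
    print(f"\nblock large-on-{side}: bias {fit.bias:+.4f}, slope {fit.slope:.1f}, "
          f"lapses ({fit.lapse_low:.3f}, {fit.lapse_high:.3f})")

print(f"\nreward-block shift (bias_L-block - bias_R-block): "
      f"{res['reward_shift']:+.4f} signed-contrast units")
# positive = the psychometric curve moved toward the larger-reward side
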