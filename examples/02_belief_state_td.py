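"""Confidence-scaled TD errors of the belief-state observer.

The observer sees a noisy percept of the signed contrast, forms a
posterior over stimulus side, chooses the side with the larger
posterior-weighted value, and carries a decision confidence.  Expected
value V = confidence x value(chosen side); the stimulus-time TD error is
V minus the session mean of V, and the outcome-time TD error is the
received reward minus V.
"""

import lateraldopa as ld

task = ld.TaskConfig()
observer = ld.ObserverParams()
trials = ld.generate_trials(task, observer, 50_000, seed=1)
ch = trials[trials.choice.isin(["L", "R"])]

print("stimulus-time TD error by contrast (correct trials):")
correct = ch[ch.correct & (ch.contrast > 0)]
print(correct.groupby("contrast")["delta_stim"].mean().round(3).to_string())
# nondecreasing in contrast: higher contrast -> higher confidence -> larger V

sub = ch[ch.contrast == 0.25]
print(f"\ndelta_stim at 25% contrast  correct: "
      f"{sub.loc[sub.correct, 'delta_stim'].mean():+.3f}   "
      f"error: {sub.loc[~sub.correct, 'delta_stim'].mean():+.3f}")
# correct > error before the outcome: errors follow weak, misleading percepts

print("\noutcome-time TD error on rewarded trials, by contrast:")
rew = ch[ch.reward_volume > 0]
print(rew.groupby("contrast")["delta_outcome"].mean().round(3).to_string())
# largest at zero contrast, where confidence is pinned at 0.5 and the
# reward is only half-predicted; near zero at high contrast

print(f"\nmean outcome TD error over all trials: {ch.delta_outcome.mean():+.4f}")
# ~0: a calibrated observer's rewards are, on average, fully predicted
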