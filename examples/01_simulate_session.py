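"""Simulate one behavioral + photometry session and inspect its structure.

The generator produces a trial table (stimulus side/contrast, reward
block, the belief-state observer's choice and outcome, event times) and a
two-channel photometry recording whose calcium transients have known
per-trial amplitudes.
"""

import lateraldopa as ld

task = ld.TaskConfig()            # 1.4/2.4 ul rewards, 100-500 trial blocks
observer = ld.ObserverParams()    # percept noise sigma = 0.15
photo = ld.PhotometryConfig(profile="DMS", hemisphere="L")

session = ld.generate_session(task, observer, photo, n_trials=400, seed=0)
trials = session.trials

print(f"{len(trials)} trials, {session.time[-1]:.0f} s of recording "
      f"at {session.sampling_rate:.0f} Hz")
print(f"blocks: {trials['block_id'].nunique()} "
      f"(large-reward side per block: "
      f"{trials.groupby('block_id')['large_reward_side'].first().tolist()})")
print(f"accuracy on stimulus trials: "
      f"{trials.loc[trials.contrast > 0, 'correct'].mean():.3f}")
zc = trials[trials.contrast == 0]
print(f"zero-contrast trials rewarded: {(zc.reward_volume > 0).mean():.3f} "
      "(programmed 0.5, independent of choice)")

# ground truth: left-hemisphere DMS responds only to right-side stimuli
amp = session.truth_amplitudes
right = trials.stimulus_side == "R"
print(f"mean generative stimulus amplitude  contra (R): "
      f"{amp.loc[right.values, 'stimulus'].mean():.3f}   "
      f"ipsi (L): {amp.loc[(trials.stimulus_side == 'L').values, 'stimulus'].mean():.3f}")
# Contralateral stimuli drive DFF transients scaled by contrast; ipsilateral
# stimuli drive nothing -- the lateralization every analysis must recover.
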