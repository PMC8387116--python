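"""Nested cross-validated regression: which trial features are needed?

Per-trial stimulus responses are regressed on contralateral contrast (c),
ipsilateral contrast (i) and pending reward value (v).  The full model
and all six reduced models are scored by held-out explained variance
under identical 5-fold splits.
"""

import lateraldopa as ld
from lateraldopa import regression as reg
from lateraldopa.pipeline import process_session

task, observer = ld.TaskConfig(), ld.ObserverParams()

# lateralized session: only contralateral contrast drives the response
photo = ld.PhotometryConfig(profile="DMS", hemisphere="L",
                            noise_sd=0.002, artifact_rate=0.02)
session = ld.generate_session(task, observer, photo, 500, seed=3)
trials = process_session(session)["trials"]
ok = trials.resp_stim.notna()
table = reg.compare_nested(trials[ok], trials.loc[ok, "resp_stim"].to_numpy(),
                           "L", k=5, seed=0)
print("lateralized (DMS-like) session:")
print(table[["model", "explained_variance", "aic"]].round(4).to_string(index=False))
# the c-only model matches the full model: contralateral contrast suffices

# full-model session: c, i and v all drive the response linearly
trials2 = ld.generate_trials(task, observer, 500, seed=4)
y = ld.linear_response_truth(
    trials2, "L",
    {"contra_contrast": 2.0, "ipsi_contrast": 1.5, "reward_value": 0.8},
    noise_sd=0.2, seed=5,
)
table2 = reg.compare_nested(trials2, y, "L", k=5, seed=0)
print("\nfull-model (VS-like) session:")
print(table2[["model", "explained_variance", "aic"]].round(4).to_string(index=False))
# every reduced model loses held-out EV: all three regressors are necessary
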