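# lateraldopa

Simulation and analysis of striatal dopamine-axon fiber photometry during
a two-alternative forced-choice (2AFC) visual decision task with
asymmetric rewards.

Dopamine axons in dorsomedial striatum (DMS) respond to contralateral —
but not ipsilateral — visual stimuli and to rewarded contralateral
actions, while axons in ventral striatum (VS) carry confidence-scaled
reward prediction errors that are independent of stimulus side. Testing
claims like these requires a pipeline that goes from raw two-channel
fluorescence to event-aligned responses, trial-by-trial regressions and a
normative model — and every stage of that pipeline can fail silently.
`lateraldopa` packages the full analysis chain together with a synthetic
session generator whose ground truth is known exactly, so each stage can
be validated end to end: if the analysis cannot recover what the
generator put in, it cannot be trusted on recordings.

It is intended for systems-neuroscience researchers analyzing fiber
photometry from decision tasks, and for anyone who wants a worked,
testable reference implementation of these analyses.

## What is inside

- **Session synthesis** — trial tables for a head-fixed steering-wheel
  task (gratings of contrast 0–0.5 left or right; 1.4 vs 2.4 µl rewards
  switching sides in blocks of 100–500 trials; zero-contrast trials
  rewarded at random with probability 0.5; a no-movement variant with a
  1.5 s hold for 2 µl), plus two-channel photometry traces with shared
  bleaching, motion artifacts and white noise, and per-frame 2D pupil
  positions.
- **Belief-state TD model** — a signal-detection observer: percept
  x̂ = x + ε, ε ~ N(0, σ²) of the signed contrast x; posterior
  P(right | x̂) by Bayes rule over sides and contrast levels; choice by
  the value-weighted rule *choose R iff P(right | x̂)·v_R > (1 −
  P(right | x̂))·v_L*; confidence = posterior probability of the chosen
  side. Expected value V = confidence · v(chosen), stimulus-time TD error
  δ_stim = V − baseline, outcome-time TD error δ_out = r − V.
- **Photometry processing** — ratiometric correction against the
  calcium-independent control channel (ΔF/F = (signal − fitted
  control) / fitted control with a whole-session affine fit), session
  z-scoring, peri-event alignment, post-minus-pre window responses
  (−0.25–0 s vs 0.4–0.8 s), peak normalization by the session's averaged
  max-contrast response, and hemisphere-before-animal averaging.
- **Trial regression** — the model R_j = β₀ + β₁c_j + β₂i_j + β₃v_j
  (contralateral contrast, ipsilateral contrast, pending reward value;
  z-scored regressors), all six reduced models, 5-fold cross-validated
  held-out explained variance with shared folds, AIC, and the
  eye-movement control R_j = β₀ + β₁c_j + β₂i_j + β₃p_j with pupil
  position p_j (median-filtered, PCA-projected, z-scored).
- **Behavior** — psychometric tables by reward block, lapse-logistic
  maximum-likelihood fits, and the reward-block bias shift.
- **Pipeline/CLI** — `lateraldopa run --config cfg.yaml` orchestrates
  simulate → process → regress → behavior → TD with per-stage files and a
  byte-reproducible JSON report; each stage is also its own subcommand.

## Worked example

Nested model comparison on two simulated 500-trial sessions
(`python examples/04_model_comparison.py`):

```
lateralized (DMS-like) session:
model  explained_variance        aic
    c              0.9987 -2291.4308
   ci              0.9987 -2289.4882
   cv              0.9987 -2289.9257
  civ              0.9987 -2288.1658
   iv              0.2312   945.2972
    i              0.1612   989.9649
    v              0.0045  1076.0702

full-model (VS-like) session:
model  explained_variance       aic
  civ              0.9540 -232.2144
   cv              0.8771  248.3053
   iv              0.8446  375.1638
    v              0.8228  436.4928
   ci              0.4547 1006.0092
    c              0.3276 1110.8410
    i             -0.0002 1312.7187
```

In the lateralized session only contralateral contrast drives the
response: the c-only model already matches the full model's held-out
explained variance, so the extra regressors are unnecessary. In the
session where contralateral contrast, ipsilateral contrast and reward
value all contribute, every reduced model loses explained variance — the
full model is necessary. The same dissociation the analyses are meant to
detect in recordings is recovered here from known ground truth.

The other `examples/*.py` scripts each exercise one capability (session
synthesis, the TD model's confidence signatures, photometry recovery,
the eye-movement control, psychometric shifts) and print annotated
output.

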