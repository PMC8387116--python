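# Methods

This note documents the models, the generative assumptions, the
parameter choices and the known limitations of `lateraldopa`.

## Task model

The simulated task is a head-fixed 2AFC contrast-detection task. On each
trial a grating of contrast c ∈ {0, 0.125, 0.25, 0.5} (configurable;
zero-contrast trials carry no stimulus) appears on the left or right,
chosen uniformly. Correct choices earn water: 1.4 µl on one side and
2.4 µl on the other, with the large-reward side alternating between
blocks whose lengths are drawn uniformly from 100–500 trials (the final
block is truncated by the session end). Zero-contrast trials are rewarded
with probability 0.5 regardless of choice, with the chosen side's block
volume. Trial timing: a quiescence period (≥ 0.6 s) and a 0.7 s
tone-to-stimulus delay precede each stimulus; a Go cue follows after an
open-loop delay drawn from 0.6–1.8 s; the reaction time is a lognormal
placeholder (median 0.3 s, log-SD 0.35 — real reaction-time
distributions for this task are not modeled), and the outcome lands a
fixed 0.25 s movement duration after action onset. The no-movement
variant replaces the choice with a per-trial hold success (probability
0.5, matching typical hold rates near 40–60%); successful holds are
rewarded 2 µl at stimulus + 1.5 s and have no action event.

## Belief-state observer and TD errors

The observer receives a percept x̂ = x + ε of the signed contrast x
(negative = left), with ε ~ N(0, σ²) and σ = 0.15 by default — a value
that yields > 90% accuracy at high contrast and near-chance performance
at the lowest nonzero contrast, matching well-trained performance on
this task. The posterior that the stimulus is on the right uses Bayes
rule with a uniform prior over sides and over the *nonzero* contrast
levels and equal-variance Gaussian likelihoods; σ = 0 is treated as a
limit (posterior = sign of the percept). The choice maximizes
posterior-weighted value, v_L and v_R being the current block's volumes;
exact ties are resolved by a fair coin. Confidence is the posterior
probability of the chosen side, overridden to 0.5 on zero-contrast
trials because reward there is choice-independent by design.

The TD model has two within-trial time points. With V = confidence ×
v(chosen side):

- δ_stim = V − B, where the baseline B is the session mean of V by
  default (`baseline_mode="mean_expected_value"`), mirroring
  baseline-subtracted photometry responses; B = 0 is available.
- δ_out = r − V, an exact identity used directly in tests.

Values are static within a block (no trial-by-trial learning); the block
switch simply swaps v_L and v_R. Because the observer's prior matches
the generative statistics, δ_out has mean zero over many trials — the
calibration property the acceptance checks measure. There is no
continuous time axis within a trial; the model makes no claim about
ramps or latencies.

## Ground-truth response profiles

Each synthetic session carries per-trial generative amplitudes for
stimulus, action and outcome transients:

- **DMS profile** (lateralized): stimulus amplitude = 2.0 × contrast for
  contralateral stimuli, 0 for ipsilateral and zero-contrast trials;
  action amplitude = 0.8 for rewarded contralateral actions and 0 for
  unrewarded ones (a config scalar allows a nonzero error-trial
  amplitude); no outcome response.
- **VS profile**: stimulus amplitude = 0.3 × δ_stim and outcome
  amplitude = 0.3 × δ_out, side-independent; no action response. The
  0.3 gain keeps ΔF/F transients within a plausible GCaMP range given
  values in µl.

## Trace synthesis

truth_dff(t) is the sum of amplitude-scaled double-exponential kernels
(rise 0.1 s, decay 1.0 s, peak-normalized — GCaMP6m-like timescales; not
a biophysical model) at the event times. The signal channel is
baseline · e^(−t/τ_bleach) · (1 + truth_dff) + artifact + noise with
baseline 10 a.u. and τ_bleach 3600 s; the control channel shares the
same single bleaching exponential and the same artifact event times
(Poisson, 0.02 events/s, amplitude 0.5, channel ratio 1.0) but no
calcium term. Sampling is 100 Hz; noise is white Gaussian (SD 0.002
a.u.). The control baseline defaults to the signal baseline, making the
clean signal–control relation exactly affine; this is the modeling
choice that justifies the affine isosbestic fit below. Pupil positions
are a mean-reverting 2D random walk at 30 Hz, with an optional
stimulus-locked horizontal deflection whose sign follows the stimulus
side (`coupling=0` gives task-independent gaze).

What the generator deliberately omits: wheel kinematics, video, licking,
slow neuromodulatory drifts, hemodynamic contamination, non-shared
artifacts, and session-to-session kernel variability. Passing tests
therefore demonstrate that the analysis chain is correct and unbiased
under its stated assumptions, not that those assumptions hold in any
particular recording.

## Photometry processing

ΔF/F = (signal − fitted control) / fitted control, where the fit is an
affine (slope + intercept) least squares of the control onto the signal
over the whole session. A slope-only variant was considered; the
intercept is kept because channel offsets are common and the affine fit
is exact under the generator's shared-bleach model. Degenerate cases
(constant control, non-positive fitted baseline, zero-variance trace)
raise instead of silently proceeding. Alignment uses nearest-sample
lookup on the uniform grid (no interpolation; ≤ 5 ms bias at 100 Hz) and
half-open lag windows [a, b), with lag 0 on the post side. Windowed
responses are mean(0.4–0.8 s) − mean(−0.25–0 s); the alternative
0.1–0.4 s post window is a parameter. The normalization peak is the
maximum of the trial-averaged max-contrast stimulus-aligned trace over
lags (0, 1.5] (window not externally specified; configurable); sessions
with a non-positive peak are flagged by an exception rather than
rescaled. Aggregation relabels stimuli/actions contra/ipsi per recorded
hemisphere, averages hemispheres within animal first, then takes an
unweighted mean across animals.

## Regression and model comparison

The full design is R_j ~ c_j + i_j + v_j: each trial contributes its
contrast to exactly one of c/i per the recorded hemisphere (zero to both
on zero-contrast trials), and v_j is the pending outcome volume (0 on
error trials). Columns are z-scored by default; zero-variance columns
are dropped with a logged warning (standardization changes coefficients
but provably not held-out EV, which is tested). OLS and standard errors
come from statsmodels; rank-deficient designs raise with the collinear
columns named. Cross-validation uses seeded unstratified 5-fold random
partitions (sklearn KFold), identical across the seven nested models;
held-out EV is 1 − SS_res/SS_tot with the held-out mean in SS_tot, and
can be negative. AIC on the full-data fit is reported as the secondary
criterion. The pupil control replaces v_j with p_j, the mean 1-D pupil
position over the response window; the 1-D position is a 1 s median
filter per coordinate, projection onto the leading eigenvector of the
2×2 covariance (sign fixed so the x-loading is positive), then z-scored.

## Psychometrics

Choices are binned by signed contrast and block type; the curve family
is a lapse logistic ψ(x) = λ_low + (1 − λ_low − λ_high) / (1 +
e^(−s(x − b))) fit by bounded L-BFGS-B on the binomial likelihood from a
deterministic start (λ ∈ [0, 0.3], slope ∈ (0, 200]). The reward shift
is b(large-on-L block) − b(large-on-R block); positive means the curve
moved toward the large-reward side in both blocks.

## Problem sizes and determinism

Default analysis sizes were chosen so that every property is measured
with comfortable statistical margin while the whole suite stays quick:
single-session checks use 300–500 trials (the range of real sessions),
coverage/selection rates use 100 seeded repeats, and calibration checks
use 10⁴–10⁵ trials. All randomness flows through numpy Generators seeded
per stage via SeedSequence spawning, so identical configs give
bit-identical sessions, and the pipeline's JSON report (sorted keys,
fixed float repr, no timestamps) is byte-identical across reruns.

## Known limitations

- The observer is static within blocks; no learning dynamics, lapses or
  history effects in choice generation (the psychometric lapse
  parameters exist only in the descriptive fit).
- The TD model has two time points per trial; it cannot address
  within-trial temporal structure such as ramping.
- The isosbestic fit assumes a shared, stationary artifact/bleach
  subspace; wavelength-specific artifacts are not modeled and would not
  be removed.
- No hierarchical/mixed-effects regression: sessions are fit
  independently and summarized by unweighted averages.
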