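"""Synthetic session generator: trials, ground-truth amplitudes, traces, pupil.

Every downstream analysis in this package is validated against sessions
produced here, where the generative amplitudes are known exactly.  The
generator emulates the structure of the task and recording — block-wise
asymmetric rewards, a belief-state decision maker, two-channel photometry
with shared bleaching and motion artifacts, and eye-position video reduced
to per-frame pupil centers — without any biophysical detail.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ObserverParams, PhotometryConfig, TaskConfig
from . import observer as obs

__all__ = [
    "SyntheticSession",
    "generate_trials",
    "ground_truth_amplitudes",
    "synthesize_traces",
    "generate_pupil",
    "generate_session",
    "linear_response_truth",
    "double_exp_kernel",
]

#: columns attached to the trial table by the generating observer
OBSERVER_COLUMNS = (
    "percept",
    "p_right",
    "confidence",
    "expected_value",
    "delta_stim",
    "delta_outcome",
)


@dataclass
class SyntheticSession:
    """A complete simulated recording session with ground truth attached."""

    trials: pd.DataFrame
    time: np.ndarray
    signal_channel: np.ndarray
    control_channel: np.ndarray
    truth_dff: np.ndarray
    truth_amplitudes: pd.DataFrame  # columns: stimulus, action, outcome
    seed: int
    pupil_xy: np.ndarray | None = None
    pupil_frame_rate: float | None = None
    animal: str = "m0"
    hemisphere: str = "L"
    profile: str = "VS"
    meta: dict = field(default_factory=dict)

    @property
    def sampling_rate(self) -> float:
        return 1.0 / (self.time[1] - self.time[0])


def _block_lengths(rng: np.random.Generator, n_trials: int, lo: int, hi: int) -> list[int]:
    lengths = []
    total = 0
    while total < n_trials:
        n = int(rng.integers(lo, hi + 1))
        lengths.append(n)
        total += n
    lengths[-1] -= total - n_trials
    if lengths[-1] == 0:
        lengths.pop()
    return lengths


def generate_trials(
    config: TaskConfig,
    observer: ObserverParams,
    n_trials: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a session's trial table.

    Reward blocks alternate the large-reward side with lengths drawn
    uniformly from ``config.block_length_range``.  Stimulus side and
    contrast are drawn uniformly at random; choices come from the
    belief-state observer with block-dependent values.  Zero-contrast
    trials are rewarded with probability ``zero_contrast_reward_prob``
    independent of the choice.  In no-movement mode a per-trial hold
    success replaces the choice and successful trials have no action.

    The generating observer's internals (percept, posterior, confidence,
    expected value and the two TD errors) are attached as extra columns so
    ground-truth amplitudes can be derived deterministically later.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if len(config.contrast_levels) == 0:
        raise ValueError("contrast_levels is empty")
    rng = np.random.default_rng(seed)

    lo, hi = config.block_length_range
    lengths = _block_lengths(rng, n_trials, lo, hi)
    first_large = "L" if rng.random() < 0.5 else "R"
    large_side = []
    for b, n in enumerate(lengths):
        side = first_large if b % 2 == 0 else ("R" if first_large == "L" else "L")
        large_side.extend([side] * n)
    block_id = np.repeat(np.arange(len(lengths)), lengths)

    contrasts = rng.choice(config.contrast_levels, size=n_trials)
    sides = np.where(contrasts == 0, "none", rng.choice(["L", "R"], size=n_trials))

    small, large = config.reward_small, config.reward_large
    rows = []
    t = 5.0  # lead-in so pre-event windows fit
    for j in range(n_trials):
        contrast = float(contrasts[j])
        side = str(sides[j])
        big = large_side[j]
        vol_for = {
            "L": large if big == "L" else small,
            "R": large if big == "R" else small,
        }
        stim_time = t
        rec: dict = {
            "index": j,
            "block_id": int(block_id[j]),
            "large_reward_side": big,
            "stimulus_side": side,
            "contrast": contrast,
            "stimulus_time": stim_time,
        }
        if config.mode == "choice":
            block_obs = observer.with_values(value_L=vol_for["L"], value_R=vol_for["R"])
            sc = contrast * (1 if side == "R" else -1 if side == "L" else 0)
            belief = obs.evaluate_trial(sc, block_obs, rng)
            go_cue = stim_time + rng.uniform(*config.open_loop_range)
            rt = config.reaction_time_median * np.exp(
                rng.normal(0.0, config.reaction_time_sigma)
            )
            action_time = go_cue + rt
            outcome_time = action_time + config.movement_duration
            if contrast == 0:
                rewarded = rng.random() < config.zero_contrast_reward_prob
                correct = rewarded
            else:
                correct = belief.choice == side
                rewarded = correct
            reward = vol_for[belief.choice] if rewarded else 0.0
            v = belief.confidence * (
                block_obs.value_R if belief.choice == "R" else block_obs.value_L
            )
            rec.update(
                go_cue_time=go_cue,
                action_time=action_time,
                choice=belief.choice,
                correct=bool(correct),
                reward_volume=float(reward),
                outcome_time=outcome_time,
                percept=belief.percept,
                p_right=belief.p_right,
                confidence=belief.confidence,
                expected_value=v,
                delta_outcome=float(reward) - v,
            )
        else:  # no_movement
            held = rng.random() < config.hold_success_prob
            if held:
                outcome_time = stim_time + config.no_movement_hold
                reward = config.no_movement_reward
                rec.update(
                    go_cue_time=np.nan,
                    action_time=np.nan,
                    choice="none",
                    correct=True,
                    reward_volume=float(reward),
                    outcome_time=outcome_time,
                )
            else:
                abort_t = stim_time + rng.uniform(0.05, config.no_movement_hold)
                rec.update(
                    go_cue_time=np.nan,
                    action_time=abort_t,
                    choice="none",
                    correct=False,
                    reward_volume=0.0,
                    outcome_time=abort_t,
                )
            rec.update(
                percept=np.nan,
                p_right=np.nan,
                confidence=np.nan,
                expected_value=np.nan,
                delta_outcome=np.nan,
            )
        rows.append(rec)
        iti = config.quiescence_min + config.tone_to_stim_delay + rng.uniform(
            0.0, config.iti_jitter
        )
        t = rec["outcome_time"] + 2.0 + iti  # 2 s post-outcome dwell

    trials = pd.DataFrame(rows)
    if config.mode == "choice":
        baseline = (
            trials["expected_value"].mean()
            if observer.baseline_mode == "mean_expected_value"
            else 0.0
        )
        trials["delta_stim"] = trials["expected_value"] - baseline
    else:
        trials["delta_stim"] = np.nan
    return trials


def ground_truth_amplitudes(
    trials: pd.DataFrame,
    photo: PhotometryConfig,
    observer: ObserverParams | None = None,
) -> pd.DataFrame:
    """Per-trial generative response amplitudes at stimulus, action and outcome.

    DMS profile (lateralized): stimulus amplitude = stim_gain x contrast
    for contralateral stimuli, 0 otherwise; action amplitude =
    ``action_amplitude`` for rewarded contralateral actions (the
    error-trial amplitude is a separate, default-zero scalar); outcome
    amplitude = 0.

    VS profile (prediction errors): stimulus amplitude = vs_gain x
    stimulus-time TD error, side-independent; action amplitude = 0;
    outcome amplitude = vs_gain x outcome-time TD error.
    """
    hemi = photo.hemisphere
    contra = "R" if hemi == "L" else "L"
    n = len(trials)
    amp = pd.DataFrame(
        {"stimulus": np.zeros(n), "action": np.zeros(n), "outcome": np.zeros(n)},
        index=trials.index,
    )
    if photo.profile == "DMS":
        is_contra_stim = (trials["stimulus_side"] == contra).to_numpy()
        amp["stimulus"] = np.where(
            is_contra_stim, photo.stim_gain * trials["contrast"].to_numpy(), 0.0
        )
        if "choice" in trials:
            is_contra_action = (trials["choice"] == contra).to_numpy()
            rewarded = (trials["reward_volume"] > 0).to_numpy()
            has_action = (
                trials["action_time"].notna().to_numpy()
                if "action_time" in trials
                else np.ones(n, bool)
            )
            amp["action"] = np.where(
                is_contra_action & has_action,
                np.where(
                    rewarded, photo.action_amplitude, photo.error_action_amplitude
                ),
                0.0,
            )
    elif photo.profile == "VS":
        if "delta_stim" not in trials or trials["delta_stim"].isna().all():
            if observer is None:
                raise ValueError(
                    "VS profile requires observer columns in the trial table "
                    "or an ObserverParams to recompute them"
                )
            sim = obs.simulate_observer(trials, observer, seed=0)
            delta_stim = sim["delta_stim"].to_numpy()
            delta_outcome = sim["delta_outcome"].to_numpy()
        else:
            delta_stim = trials["delta_stim"].to_numpy()
            delta_outcome = trials["delta_outcome"].to_numpy()
        amp["stimulus"] = photo.vs_gain * delta_stim
        amp["outcome"] = photo.vs_gain * delta_outcome
    else:  # pragma: no cover - config validation blocks this
        raise ValueError(f"unknown profile {photo.profile!r}")
    return amp


def linear_response_truth(
    trials: pd.DataFrame,
    hemisphere: str,
    beta: dict[str, float],
    noise_sd: float = 0.0,
    intercept: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Per-trial scalar responses generated linearly from trial features.

    ``beta`` maps regressor names (``contra_contrast``, ``ipsi_contrast``,
    ``reward_value``) to generative slopes on the *raw* (unstandardized)
    features.  Used as ground truth for regression parameter-recovery and
    model-selection checks, where the generative model must be exactly the
    fitted family.
    """
    contra_side = "R" if hemisphere == "L" else "L"
    contrast = trials["contrast"].to_numpy(dtype=float)
    side = trials["stimulus_side"].to_numpy()
    feats = {
        "contra_contrast": np.where(side == contra_side, contrast, 0.0),
        "ipsi_contrast": np.where(
            side == ("L" if contra_side == "R" else "R"), contrast, 0.0
        ),
        "reward_value": trials["reward_volume"].to_numpy(dtype=float),
    }
    y = np.full(len(trials), float(intercept))
    for name, b in beta.items():
        y = y + b * feats[name]
    if noise_sd > 0:
        y = y + np.random.default_rng(seed).normal(0.0, noise_sd, size=len(y))
    return y


def double_exp_kernel(t: np.ndarray, rise: float, decay: float) -> np.ndarray:
    """Difference-of-exponentials transient, peak-normalized to 1 at
    t_peak = rise*decay/(decay-rise) * log(decay/rise); zero for t < 0."""
    k = np.where(t >= 0, np.exp(-np.maximum(t, 0) / decay) - np.exp(-np.maximum(t, 0) / rise), 0.0)
    t_peak = rise * decay / (decay - rise) * np.log(decay / rise)
    peak = np.exp(-t_peak / decay) - np.exp(-t_peak / rise)
    return k / peak


def _add_transients(
    trace: np.ndarray,
    times: np.ndarray,
    amplitudes: np.ndarray,
    fs: float,
    rise: float,
    decay: float,
) -> None:
    """Add amplitude-scaled kernels at the given event times, in place."""
    kern_len = int(np.ceil((rise + 8 * decay) * fs))
    tk = np.arange(kern_len) / fs
    kernel = double_exp_kernel(tk, rise, decay)
    n = trace.shape[0]
    for t0, a in zip(times, amplitudes):
        if a == 0 or not np.isfinite(t0):
            continue
        i0 = int(round(t0 * fs))
        if i0 >= n:
            continue
        stop = min(n, i0 + kern_len)
        trace[i0:stop] += a * kernel[: stop - i0]


def synthesize_traces(
    trials: pd.DataFrame,
    amplitudes: pd.DataFrame,
    photo: PhotometryConfig,
    duration: float | None = None,
    seed: int = 0,
) -> SyntheticSession:
    """Render two-channel photometry traces from per-trial event amplitudes.

    truth_dff is the sum of amplitude-scaled double-exponential kernels at
    stimulus/action/outcome times.  The signal channel carries the
    bleaching baseline modulated by (1 + truth_dff) plus motion artifacts
    and white noise; the control channel carries the same bleaching and
    the same artifact event times (scaled by ``artifact_channel_ratio``)
    but no calcium signal.
    """
    last_event = float(trials["outcome_time"].max())
    if duration is None:
        duration = last_event + 10.0
    if duration <= last_event:
        raise ValueError(
            f"duration {duration} s is shorter than the trial span ({last_event:.1f} s)"
        )
    fs = photo.sampling_rate
    n = int(round(duration * fs))
    time = np.arange(n) / fs
    rng = np.random.default_rng(seed)

    truth = np.zeros(n)
    for event, col in (
        ("stimulus_time", "stimulus"),
        ("action_time", "action"),
        ("outcome_time", "outcome"),
    ):
        if event in trials:
            _add_transients(
                truth,
                trials[event].to_numpy(dtype=float),
                amplitudes[col].to_numpy(dtype=float),
                fs,
                photo.kernel_rise,
                photo.kernel_decay,
            )

    artifact = np.zeros(n)
    n_art = rng.poisson(photo.artifact_rate * duration)
    art_times = np.sort(rng.uniform(0, duration, size=n_art))
    _add_transients(
        artifact,
        art_times,
        np.full(n_art, photo.artifact_amplitude),
        fs,
        photo.kernel_rise,
        photo.kernel_decay,
    )

    bleach = np.exp(-time / photo.bleach_tau)
    signal = (
        photo.baseline * bleach * (1.0 + truth)
        + artifact
        + rng.normal(0.0, photo.noise_sd, size=n)
    )
    control = (
        photo.effective_control_baseline * bleach
        + photo.artifact_channel_ratio * artifact
        + rng.normal(0.0, photo.noise_sd, size=n)
    )
    return SyntheticSession(
        trials=trials,
        time=time,
        signal_channel=signal,
        control_channel=control,
        truth_dff=truth,
        truth_amplitudes=amplitudes,
        seed=seed,
        hemisphere=photo.hemisphere,
        profile=photo.profile,
        meta={"artifact_times": art_times},
    )


def generate_pupil(
    trials: pd.DataFrame,
    coupling: float = 0.0,
    frame_rate: float = 30.0,
    duration: float | None = None,
    seed: int = 0,
    walk_sd: float = 0.5,
    walk_theta: float = 0.05,
) -> np.ndarray:
    """Per-frame 2D pupil-center positions (px) for the session.

    Baseline gaze is a mean-reverting 2D random walk.  With ``coupling``
    nonzero, each stimulus adds a horizontal deflection toward the
    stimulus side (positive x = right), scaled by coupling x contrast.
    ``coupling=0`` yields gaze completely independent of the task.
    """
    if frame_rate <= 0:
        raise ValueError("frame_rate must be > 0")
    if duration is None:
        duration = float(trials["outcome_time"].max()) + 10.0
    rng = np.random.default_rng(seed)
    n = int(np.ceil(duration * frame_rate))
    steps = rng.normal(0.0, walk_sd, size=(n, 2))
    xy = np.zeros((n, 2))
    for i in range(1, n):  # OU recursion keeps gaze bounded
        xy[i] = (1 - walk_theta) * xy[i - 1] + steps[i]
    if coupling != 0:
        deflection = np.zeros(n)
        sign = {"L": -1.0, "R": 1.0, "none": 0.0}
        times = trials["stimulus_time"].to_numpy(dtype=float)
        amps = np.array(
            [
                coupling * c * sign[s]
                for c, s in zip(trials["contrast"], trials["stimulus_side"])
            ]
        )
        _add_transients(deflection, times, amps, frame_rate, 0.1, 1.0)
        xy[:, 0] += deflection
    return xy


def generate_session(
    task: TaskConfig,
    observer: ObserverParams,
    photo: PhotometryConfig,
    n_trials: int,
    seed: int = 0,
    pupil_coupling: float | None = None,
    pupil_frame_rate: float = 30.0,
    animal: str = "m0",
) -> SyntheticSession:
    """Convenience: trials -> amplitudes -> traces (+ pupil) in one call.

    Derives independent sub-seeds for the trial, trace and pupil stages
    from ``seed`` so stages remain individually reproducible.
    """
    ss = np.random.SeedSequence(seed)
    s_trials, s_traces, s_pupil = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3))
    trials = generate_trials(task, observer, n_trials, seed=s_trials)
    amps = ground_truth_amplitudes(trials, photo, observer)
    session = synthesize_traces(trials, amps, photo, seed=s_traces)
    if pupil_coupling is not None:
        session.pupil_xy = generate_pupil(
            trials,
            coupling=pupil_coupling,
            frame_rate=pupil_frame_rate,
            duration=session.time[-1] + 1.0 / photo.sampling_rate,
            seed=s_pupil,
        )
        session.pupil_frame_rate = pupil_frame_rate
    session.animal = animal
    return session
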