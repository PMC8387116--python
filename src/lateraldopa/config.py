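"""Configuration objects for task simulation, photometry synthesis and the observer.

All dataclasses validate their invariants in ``__post_init__`` and raise
:class:`ConfigError` listing every violation at once, so a bad YAML file
produces one comprehensive message rather than a cascade of retries.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from typing import Sequence


class ConfigError(ValueError):
    """One or more configuration invariants are violated."""

    def __init__(self, problems: Sequence[str]):
        self.problems = list(problems)
        super().__init__("; ".join(self.problems))


def _check(problems: list[str]) -> None:
    if problems:
        raise ConfigError(problems)


@dataclass
class TaskConfig:
    """Parameters of the 2AFC steering-wheel task.

    The defaults encode the published task: water rewards of 1.4 or 2.4 ul
    depending on block and stimulus side, reward blocks of 100-500 trials,
    a 0.6-1.8 s open-loop delay between stimulus and Go cue, zero-contrast
    trials rewarded at random with probability 0.5, and a 1.5 s hold
    requirement (2 ul reward) in the no-movement variant.
    """

    contrast_levels: tuple[float, ...] = (0.0, 0.125, 0.25, 0.5)
    reward_small: float = 1.4
    reward_large: float = 2.4
    block_length_range: tuple[int, int] = (100, 500)
    zero_contrast_reward_prob: float = 0.5
    quiescence_min: float = 0.6
    tone_to_stim_delay: float = 0.7
    open_loop_range: tuple[float, float] = (0.6, 1.8)
    mode: str = "choice"  # {"choice", "no_movement"}
    no_movement_hold: float = 1.5
    no_movement_reward: float = 2.0
    hold_success_prob: float = 0.5
    # lognormal reaction-time placeholder (s): exp(N(mu, sigma))
    reaction_time_median: float = 0.3
    reaction_time_sigma: float = 0.35
    movement_duration: float = 0.25
    iti_jitter: float = 0.5

    def __post_init__(self):
        p = []
        self.contrast_levels = tuple(sorted(float(c) for c in self.contrast_levels))
        if len(self.contrast_levels) == 0:
            p.append("contrast_levels must be nonempty")
        if any(not (0.0 <= c <= 1.0) for c in self.contrast_levels):
            p.append("every contrast must lie in [0, 1]")
        if not (self.reward_large > self.reward_small > 0):
            p.append("must have reward_large > reward_small > 0")
        lo, hi = self.block_length_range
        if not (1 <= lo <= hi):
            p.append("block_length_range must satisfy 1 <= low <= high")
        self.block_length_range = (int(lo), int(hi))
        if not (0.0 <= self.zero_contrast_reward_prob <= 1.0):
            p.append("zero_contrast_reward_prob must lie in [0, 1]")
        if self.mode not in ("choice", "no_movement"):
            p.append(f"mode must be 'choice' or 'no_movement', got {self.mode!r}")
        if not (0.0 <= self.hold_success_prob <= 1.0):
            p.append("hold_success_prob must lie in [0, 1]")
        olo, ohi = self.open_loop_range
        if not (0.0 <= olo <= ohi):
            p.append("open_loop_range must satisfy 0 <= low <= high")
        self.open_loop_range = (float(olo), float(ohi))
        _check(p)

    @property
    def nonzero_contrasts(self) -> tuple[float, ...]:
        return tuple(c for c in self.contrast_levels if c > 0)


@dataclass
class PhotometryConfig:
    """Parameters of the synthetic two-channel photometry recording.

    ``profile`` selects the ground-truth response model: ``"DMS"`` gives
    lateralized contralateral stimulus/action responses; ``"VS"`` gives
    side-independent confidence-scaled prediction-error responses.
    The double-exponential kernel defaults (0.1 s rise, 1.0 s decay)
    mimic GCaMP6m transient timescales.
    """

    sampling_rate: float = 100.0
    kernel_rise: float = 0.1
    kernel_decay: float = 1.0
    noise_sd: float = 0.002
    artifact_rate: float = 0.02
    artifact_amplitude: float = 0.5
    artifact_channel_ratio: float = 1.0
    bleach_tau: float = 3600.0
    baseline: float = 10.0
    control_baseline: float | None = None  # None -> same as baseline
    profile: str = "VS"  # {"VS", "DMS"}
    hemisphere: str = "L"  # {"L", "R"}
    stim_gain: float = 2.0  # DMS: dff per unit contralateral contrast
    action_amplitude: float = 0.8  # DMS: rewarded contralateral action
    error_action_amplitude: float = 0.0  # DMS: unrewarded contralateral action
    vs_gain: float = 0.3  # VS: dff per unit TD error (ul)

    def __post_init__(self):
        p = []
        if not self.sampling_rate > 0:
            p.append("sampling_rate must be > 0")
        if not (self.kernel_decay > self.kernel_rise > 0):
            p.append("must have kernel_decay > kernel_rise > 0")
        if not self.artifact_channel_ratio > 0:
            p.append("artifact_channel_ratio must be > 0")
        if self.profile not in ("VS", "DMS"):
            p.append(f"profile must be 'VS' or 'DMS', got {self.profile!r}")
        if self.hemisphere not in ("L", "R"):
            p.append(f"hemisphere must be 'L' or 'R', got {self.hemisphere!r}")
        if self.control_baseline is not None and not self.control_baseline > 0:
            p.append("control_baseline must be > 0 when given")
        _check(p)

    @property
    def effective_control_baseline(self) -> float:
        return self.baseline if self.control_baseline is None else self.control_baseline


@dataclass
class ObserverParams:
    """Signal-detection observer: Gaussian percept noise and side values.

    ``sigma`` is the percept noise SD in signed-contrast units.
    ``value_L`` / ``value_R`` are the water volumes (ul) at stake for a
    correct left/right choice in the current block.  ``baseline_mode``
    selects the baseline subtracted from the stimulus-time prediction
    error: ``"zero"`` or ``"mean_expected_value"`` (session mean of the
    expected value, mirroring baseline-subtracted photometry responses).
    """

    sigma: float = 0.15
    contrast_levels: tuple[float, ...] = (0.0, 0.125, 0.25, 0.5)
    value_L: float = 1.4
    value_R: float = 2.4
    zero_contrast_reward_prob: float = 0.5
    baseline_mode: str = "mean_expected_value"

    def __post_init__(self):
        p = []
        if self.sigma < 0:
            p.append("sigma must be >= 0")
        if not (self.value_L > 0 and self.value_R > 0):
            p.append("value_L and value_R must be > 0")
        if not (0.0 <= self.zero_contrast_reward_prob <= 1.0):
            p.append("zero_contrast_reward_prob must lie in [0, 1]")
        if self.baseline_mode not in ("zero", "mean_expected_value"):
            p.append(
                "baseline_mode must be 'zero' or 'mean_expected_value', "
                f"got {self.baseline_mode!r}"
            )
        self.contrast_levels = tuple(sorted(float(c) for c in self.contrast_levels))
        if any(c < 0 for c in self.contrast_levels):
            p.append("contrast levels must be >= 0")
        _check(p)

    @property
    def nonzero_contrasts(self) -> tuple[float, ...]:
        return tuple(c for c in self.contrast_levels if c > 0)

    def with_values(self, value_L: float, value_R: float) -> "ObserverParams":
        return ObserverParams(
            sigma=self.sigma,
            contrast_levels=self.contrast_levels,
            value_L=value_L,
            value_R=value_R,
            zero_contrast_reward_prob=self.zero_contrast_reward_prob,
            baseline_mode=self.baseline_mode,
        )


@dataclass
class AnalysisConfig:
    """Windows (s, relative to event) and CV settings used downstream."""

    pre_window: tuple[float, float] = (-0.25, 0.0)
    post_window: tuple[float, float] = (0.4, 0.8)
    align_window: tuple[float, float] = (-1.0, 2.0)
    peak_window: tuple[float, float] = (0.0, 1.5)
    cv_folds: int = 5

    def __post_init__(self):
        p = []
        if not self.pre_window[0] < self.pre_window[1]:
            p.append("pre_window must be increasing")
        if not self.post_window[0] < self.post_window[1]:
            p.append("post_window must be increasing")
        if self.post_window[0] < self.pre_window[1]:
            p.append("post_window must start at or after pre_window end")
        if self.cv_folds < 2:
            p.append("cv_folds must be >= 2")
        _check(p)


@dataclass
class PipelineConfig:
    """Top-level configuration binding all stages together."""

    task: TaskConfig = field(default_factory=TaskConfig)
    observer: ObserverParams = field(default_factory=ObserverParams)
    photometry: PhotometryConfig = field(default_factory=PhotometryConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    n_sessions: int = 3
    n_trials: int = 300
    pupil_frame_rate: float = 30.0
    pupil_coupling: float = 0.0
    seed: int = 0

    def __post_init__(self):
        p = []
        if self.n_sessions < 1:
            p.append("n_sessions must be >= 1")
        if self.n_trials < 1:
            p.append("n_trials must be >= 1")
        if not self.pupil_frame_rate > 0:
            p.append("pupil_frame_rate must be > 0")
        _check(p)

    def to_dict(self) -> dict:
        return asdict(self)


_SECTION_TYPES = {
    "task": TaskConfig,
    "observer": ObserverParams,
    "photometry": PhotometryConfig,
    "analysis": AnalysisConfig,
}


def pipeline_config_from_dict(data: dict | None) -> PipelineConfig:
    """Build a defaulted, validated :class:`PipelineConfig` from nested dicts.

    Collects *all* violations (unknown keys and invariant failures) into a
    single :class:`ConfigError`.
    """
    data = dict(data or {})
    problems: list[str] = []
    kwargs: dict = {}
    for key, cls in _SECTION_TYPES.items():
        section = data.pop(key, {}) or {}
        if not isinstance(section, dict):
            problems.append(f"section {key!r} must be a mapping")
            continue
        known = {f.name for f in fields(cls)}
        unknown = set(section) - known
        if unknown:
            problems.append(f"unknown keys in {key!r}: {sorted(unknown)}")
        try:
            kwargs[key] = cls(**{k: v for k, v in section.items() if k in known})
        except ConfigError as e:
            problems.extend(f"{key}: {msg}" for msg in e.problems)
        except TypeError as e:  # pragma: no cover - defensive
            problems.append(f"{key}: {e}")
    top_known = {f.name for f in fields(PipelineConfig)} - set(_SECTION_TYPES)
    unknown = set(data) - top_known
    if unknown:
        problems.append(f"unknown top-level keys: {sorted(unknown)}")
    _check(problems)
    try:
        cfg = PipelineConfig(**kwargs, **{k: v for k, v in data.items() if k in top_known})
    except ConfigError as e:
        _check(list(e.problems))
    return cfg
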