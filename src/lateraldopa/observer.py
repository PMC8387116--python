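"""Belief-state observer and confidence-scaled temporal-difference errors.

The observer performs signal detection on a noisy percept of the signed
stimulus contrast (negative = left, positive = right), forms the posterior
probability that the stimulus is on the right, chooses the side with the
larger posterior-weighted value, and assigns a decision confidence — the
probability that the choice will turn out to be correct given the percept.

The within-trial TD model has two time points.  The expected value at the
stimulus is V = confidence x value(chosen side); the stimulus-time
prediction error is V minus a baseline (zero, or the session mean of V);
the outcome-time prediction error is the received reward minus V.  These
two quantities reproduce the qualitative signatures of ventral-striatal
dopamine: stimulus responses graded by contrast and upcoming reward size,
correct > error before the outcome, and rewarded-outcome responses that
are largest on the hardest (zero-contrast) trials.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ObserverParams

__all__ = [
    "BeliefState",
    "TDOutput",
    "sample_percept",
    "side_posterior",
    "choose",
    "confidence",
    "td_errors",
    "simulate_observer",
]


@dataclass
class BeliefState:
    percept: float
    p_right: float
    choice: str  # {"L", "R"}
    confidence: float


@dataclass
class TDOutput:
    delta_stim: float
    delta_outcome: float


def sample_percept(signed_contrast: float, sigma: float, rng: np.random.Generator) -> float:
    """Draw a percept: the signed contrast corrupted by Gaussian noise."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return float(signed_contrast)
    return float(signed_contrast + rng.normal(0.0, sigma))


def side_posterior(percept: float, params: ObserverParams) -> float:
    """Posterior probability the stimulus is on the right, given the percept.

    Bayes rule with a uniform prior over sides and over the nonzero
    contrast levels, and an equal-variance Gaussian likelihood centered at
    +/- contrast.  Antisymmetric around zero: p_right(-x) = 1 - p_right(x).
    In the sigma -> 0 limit the posterior collapses to the sign of the
    percept (1/2 at exactly zero).
    """
    contrasts = np.asarray(params.nonzero_contrasts, dtype=float)
    if contrasts.size == 0:
        raise ValueError("contrast_levels must contain at least one nonzero level")
    if params.sigma == 0:
        if percept > 0:
            return 1.0
        if percept < 0:
            return 0.0
        return 0.5
    # log-likelihoods, stabilized by subtracting the overall max
    ll_r = -0.5 * ((percept - contrasts) / params.sigma) ** 2
    ll_l = -0.5 * ((percept + contrasts) / params.sigma) ** 2
    m = max(ll_r.max(), ll_l.max())
    num = np.exp(ll_r - m).sum()
    den = num + np.exp(ll_l - m).sum()
    return float(num / den)


def choose(p_right: float, params: ObserverParams, rng: np.random.Generator | None = None) -> str:
    """Value-weighted decision rule: pick the side with larger expected value.

    R if p_right * value_R > (1 - p_right) * value_L, else L; exact ties
    are broken by a fair coin.
    """
    ev_r = p_right * params.value_R
    ev_l = (1.0 - p_right) * params.value_L
    if ev_r > ev_l:
        return "R"
    if ev_r < ev_l:
        return "L"
    if rng is None:
        rng = np.random.default_rng()
    return "R" if rng.random() < 0.5 else "L"


def confidence(p_right: float, choice: str, trial_contrast: float, params: ObserverParams) -> float:
    """Probability the choice is correct given the percept.

    On zero-contrast trials reward is delivered at random irrespective of
    choice, so confidence equals the programmed reward probability there.
    """
    if trial_contrast == 0:
        return float(params.zero_contrast_reward_prob)
    return float(p_right if choice == "R" else 1.0 - p_right)


def td_errors(
    reward_received: float,
    conf: float,
    chosen_value: float,
    baseline: float = 0.0,
) -> TDOutput:
    """Two-timepoint TD errors given confidence and the value at stake.

    V = conf * chosen_value; delta_stim = V - baseline;
    delta_outcome = reward_received - V (an exact identity by construction).
    """
    v = conf * chosen_value
    return TDOutput(delta_stim=v - baseline, delta_outcome=reward_received - v)


def _chosen_value(choice: str, params: ObserverParams) -> float:
    return params.value_R if choice == "R" else params.value_L


def evaluate_trial(
    signed_contrast: float,
    params: ObserverParams,
    rng: np.random.Generator,
) -> BeliefState:
    """Run one trial of the observer: percept -> posterior -> choice -> confidence."""
    percept = sample_percept(signed_contrast, params.sigma, rng)
    p_r = side_posterior(percept, params)
    ch = choose(p_r, params, rng)
    conf = confidence(p_r, ch, abs(signed_contrast), params)
    return BeliefState(percept=percept, p_right=p_r, choice=ch, confidence=conf)


def simulate_observer(trials: pd.DataFrame, params: ObserverParams, seed: int = 0) -> pd.DataFrame:
    """Re-run the observer over a trial table and attach TD errors.

    Expects columns ``contrast``, ``stimulus_side``, ``reward_volume`` and
    ``large_reward_side``; the per-block value assignment follows
    ``large_reward_side``.  Returns a frame with columns (index, percept,
    p_right, choice_model, confidence, delta_stim, delta_outcome).

    The stimulus-time baseline is 0 or the session mean of V depending on
    ``params.baseline_mode``.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for t in trials.itertuples():
        side = getattr(t, "stimulus_side", "none")
        sc = t.contrast * (1 if side == "R" else -1 if side == "L" else 0)
        large = getattr(t, "large_reward_side", "R")
        vl, vr = (
            (params.value_L, params.value_R)
            if params.value_R >= params.value_L
            else (params.value_R, params.value_L)
        )
        small, big = min(vl, vr), max(vl, vr)
        block_params = params.with_values(
            value_L=big if large == "L" else small,
            value_R=big if large == "R" else small,
        )
        belief = evaluate_trial(sc, block_params, rng)
        v = belief.confidence * _chosen_value(belief.choice, block_params)
        rows.append(
            {
                "index": t.index,
                "percept": belief.percept,
                "p_right": belief.p_right,
                "choice_model": belief.choice,
                "confidence": belief.confidence,
                "expected_value": v,
                "reward_volume": t.reward_volume,
            }
        )
    out = pd.DataFrame(rows)
    baseline = out["expected_value"].mean() if params.baseline_mode == "mean_expected_value" else 0.0
    out["delta_stim"] = out["expected_value"] - baseline
    out["delta_outcome"] = out["reward_volume"] - out["expected_value"]
    return out.drop(columns=["reward_volume"])
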