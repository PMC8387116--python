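"""Psychometric summaries of 2AFC choice behavior and the reward-block shift.

Choices are summarized as the probability of choosing right versus signed
contrast (negative = left stimulus), split by which side currently pays
the larger reward.  A lapse-logistic curve is fit per block type by
maximum likelihood; the horizontal displacement between the two block
fits indexes the behavioral shift toward the larger-reward side.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit

__all__ = [
    "PsychometricFit",
    "psychometric_table",
    "fit_psychometric",
    "reward_bias",
    "psychometric_curve",
]

_SLOPE_MAX = 200.0
_LAPSE_MAX = 0.3


@dataclass
class PsychometricFit:
    bias: float  # signed-contrast units; x at the curve midpoint
    slope: float  # 1/contrast
    lapse_low: float
    lapse_high: float
    nll: float
    converged: bool
    message: str = ""


def signed_contrast(trials: pd.DataFrame) -> np.ndarray:
    sign = trials["stimulus_side"].map({"L": -1.0, "R": 1.0, "none": 0.0}).to_numpy()
    return trials["contrast"].to_numpy(dtype=float) * sign


def psychometric_table(trials: pd.DataFrame) -> pd.DataFrame:
    """Fraction of rightward choices per signed contrast and block type.

    Zero-contrast trials enter at signed contrast 0 in both block types.
    Only trials with a registered choice (L or R) are counted.
    """
    done = trials[trials["choice"].isin(["L", "R"])].copy()
    if done.empty:
        raise ValueError("no completed trials with a registered choice")
    done["signed_contrast"] = signed_contrast(done)
    done["chose_right"] = (done["choice"] == "R").astype(float)
    table = (
        done.groupby(["large_reward_side", "signed_contrast"])
        .agg(n_trials=("chose_right", "size"), frac_right=("chose_right", "mean"))
        .reset_index()
    )
    return table


def psychometric_curve(x, bias, slope, lapse_low, lapse_high):
    """Lapse-logistic: psi(x) = ll + (1 - ll - lh) / (1 + exp(-slope (x - bias)))."""
    return lapse_low + (1.0 - lapse_low - lapse_high) * expit(slope * (np.asarray(x) - bias))


def fit_psychometric(table: pd.DataFrame) -> PsychometricFit:
    """Maximum-likelihood lapse-logistic fit to one block type's table.

    Expects columns ``signed_contrast``, ``n_trials``, ``frac_right``.
    Binomial likelihood, bounded L-BFGS-B from a deterministic start.
    """
    if table["signed_contrast"].nunique() < 3:
        raise ValueError("need data at >= 3 contrast levels to fit a psychometric curve")
    x = table["signed_contrast"].to_numpy(dtype=float)
    n = table["n_trials"].to_numpy(dtype=float)
    k = np.round(table["frac_right"].to_numpy(dtype=float) * n)

    def nll(theta):
        b, s, ll, lh = theta
        p = np.clip(psychometric_curve(x, b, s, ll, lh), 1e-9, 1 - 1e-9)
        return -np.sum(k * np.log(p) + (n - k) * np.log(1 - p))

    span = max(x.max() - x.min(), 1e-3)
    x0 = np.array([0.0, 4.0 / span, 0.02, 0.02])
    bounds = [
        (x.min(), x.max()),
        (1e-3, _SLOPE_MAX),
        (0.0, _LAPSE_MAX),
        (0.0, _LAPSE_MAX),
    ]
    res = minimize(nll, x0, method="L-BFGS-B", bounds=bounds)
    if not res.success and not np.isfinite(res.fun):
        raise RuntimeError(f"psychometric fit failed: {res.message}")
    b, s, ll, lh = res.x
    return PsychometricFit(
        bias=float(b),
        slope=float(s),
        lapse_low=float(ll),
        lapse_high=float(lh),
        nll=float(res.fun),
        converged=bool(res.success),
        message=str(res.message),
    )


def reward_bias(fit_blockL: PsychometricFit, fit_blockR: PsychometricFit) -> float:
    """Signed psychometric shift between the two reward blocks.

    shift = bias(large-on-left block) - bias(large-on-right block).
    Under the value-weighted decision rule the curve moves toward the
    large-reward side (leftward threshold when right pays more, and vice
    versa), so a positive shift means the behavior moved toward the
    larger-reward side in both blocks.
    """
    return float(fit_blockL.bias - fit_blockR.bias)


def analyze_behavior(trials: pd.DataFrame) -> dict:
    """Table + per-block fits + shift, as one summary dict."""
    table = psychometric_table(trials)
    fits = {}
    for side in ("L", "R"):
        sub = table[table["large_reward_side"] == side]
        if sub["signed_contrast"].nunique() >= 3:
            fits[side] = fit_psychometric(sub)
    out = {"table": table, "fits": fits}
    if "L" in fits and "R" in fits:
        out["reward_shift"] = reward_bias(fits["L"], fits["R"])
    return out
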