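"""Trial-by-trial regression, nested cross-validated model comparison, and
the pupil-position control analysis.

The full model regresses the per-trial stimulus response R_j on the
contralateral stimulus contrast c_j, the ipsilateral contrast i_j, and the
value of the pending reward v_j (0, small, large), with regressors
z-scored.  Reduced models omit one or two of the three terms; all models
are scored by held-out explained variance under identical 5-fold splits.
The eye-movement control swaps v_j for the post-stimulus mean pupil
position p_j.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.ndimage import median_filter
from sklearn.model_selection import KFold

logger = logging.getLogger(__name__)

REGRESSORS = ("contra_contrast", "ipsi_contrast", "reward_value", "pupil")
SHORT = {"contra_contrast": "c", "ipsi_contrast": "i", "reward_value": "v", "pupil": "p"}


@dataclass
class DesignSpec:
    regressors: tuple[str, ...]
    standardize: bool = True

    def __post_init__(self):
        if not self.regressors:
            raise ValueError("regressors must be nonempty")
        if len(set(self.regressors)) != len(self.regressors):
            raise ValueError("duplicate regressors")
        unknown = set(self.regressors) - set(REGRESSORS)
        if unknown:
            raise ValueError(f"unknown regressors: {sorted(unknown)}")
        self.regressors = tuple(self.regressors)

    @property
    def label(self) -> str:
        return "".join(SHORT[r] for r in self.regressors)


@dataclass
class RegressionFit:
    intercept: float
    slopes: dict[str, float]
    slope_se: dict[str, float]
    n_trials: int
    dropped: tuple[str, ...] = ()
    residuals: np.ndarray | None = None


@dataclass
class CVResult:
    model: DesignSpec
    explained_variance: float
    k: int
    seed: int
    aic: float = np.nan
    fold_ev: tuple[float, ...] = field(default_factory=tuple)


def _contra_ipsi(trials: pd.DataFrame, hemisphere: str) -> tuple[np.ndarray, np.ndarray]:
    contra_side = "R" if hemisphere == "L" else "L"
    contrast = trials["contrast"].to_numpy(dtype=float)
    side = trials["stimulus_side"].to_numpy()
    c = np.where(side == contra_side, contrast, 0.0)
    i = np.where(side == ("L" if contra_side == "R" else "R"), contrast, 0.0)
    return c, i


def build_design(
    trials: pd.DataFrame,
    responses: np.ndarray,
    spec: DesignSpec,
    hemisphere: str,
    pupil_by_trial: np.ndarray | None = None,
) -> tuple[pd.DataFrame, np.ndarray, list[str]]:
    """Assemble the design matrix for one session.

    Each trial contributes its contrast to exactly one of the contra/ipsi
    columns (zero-contrast trials to neither); ``reward_value`` is the
    pending outcome volume; ``pupil`` is the mean 1-D pupil position over
    the post-stimulus window, supplied per trial.  Columns are z-scored
    when ``spec.standardize``; zero-variance columns are dropped with a
    logged warning.

    Returns (design frame, response vector, dropped column names).
    """
    if hemisphere not in ("L", "R"):
        raise ValueError("hemisphere must be 'L' or 'R'")
    responses = np.asarray(responses, dtype=float)
    if len(responses) != len(trials):
        raise ValueError("responses must align with trials")
    c, i = _contra_ipsi(trials, hemisphere)
    columns = {}
    for name in spec.regressors:
        if name == "contra_contrast":
            columns[name] = c
        elif name == "ipsi_contrast":
            columns[name] = i
        elif name == "reward_value":
            columns[name] = trials["reward_volume"].to_numpy(dtype=float)
        elif name == "pupil":
            if pupil_by_trial is None:
                raise ValueError("pupil regressor requested but no pupil data supplied")
            columns[name] = np.asarray(pupil_by_trial, dtype=float)
    X = pd.DataFrame(columns, index=trials.index)
    dropped = [name for name in X.columns if X[name].std() == 0]
    for name in dropped:
        logger.warning("dropping zero-variance regressor %r", name)
    X = X.drop(columns=dropped)
    if spec.standardize:
        X = (X - X.mean()) / X.std()
    return X, responses, dropped


def fit_ols(X: pd.DataFrame, y: np.ndarray) -> RegressionFit:
    """Ordinary least squares with an intercept; SEs from residual variance."""
    if len(y) <= X.shape[1] + 1:
        raise ValueError("need more trials than parameters")
    Xc = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(Xc.to_numpy())
    if rank < Xc.shape[1]:
        corr = X.corr().abs()
        np.fill_diagonal(corr.values, 0)
        worst = corr.stack().idxmax() if X.shape[1] > 1 else (X.columns[0],)
        raise ValueError(f"rank-deficient design; collinear columns: {worst}")
    res = sm.OLS(y, Xc).fit()
    return RegressionFit(
        intercept=float(res.params["const"]),
        slopes={k: float(res.params[k]) for k in X.columns},
        slope_se={k: float(res.bse[k]) for k in X.columns},
        n_trials=len(y),
        residuals=np.asarray(res.resid),
    )


def _fold_indices(n: int, k: int, seed: int) -> list[np.ndarray]:
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    return [test for _, test in kf.split(np.arange(n))]


def cv_explained_variance(
    X: pd.DataFrame,
    y: np.ndarray,
    k: int = 5,
    seed: int = 0,
    folds: list[np.ndarray] | None = None,
    spec: DesignSpec | None = None,
) -> CVResult:
    """Held-out explained variance, averaged over seeded k-fold splits.

    Per fold: fit on the other k-1 folds, score the held-out fold as
    1 - SS_residual / SS_total with the held-out mean in SS_total.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < k:
        raise ValueError("need at least k trials")
    if folds is None:
        folds = _fold_indices(n, k, seed)
    evs = []
    all_idx = np.arange(n)
    for test in folds:
        if len(test) < 2:
            raise ValueError("fold with fewer than 2 trials")
        train = np.setdiff1d(all_idx, test)
        Xtr = sm.add_constant(X.iloc[train], has_constant="add")
        Xte = sm.add_constant(X.iloc[test], has_constant="add")
        beta = sm.OLS(y[train], Xtr).fit().params
        pred = Xte.to_numpy() @ beta.to_numpy()
        resid = y[test] - pred
        ss_tot = np.sum((y[test] - y[test].mean()) ** 2)
        evs.append(1.0 - np.sum(resid**2) / ss_tot)
    # full-data AIC for the secondary comparison criterion
    aic = float(sm.OLS(y, sm.add_constant(X, has_constant="add")).fit().aic)
    return CVResult(
        model=spec or DesignSpec(tuple(X.columns), standardize=False),
        explained_variance=float(np.mean(evs)),
        k=k,
        seed=seed,
        aic=aic,
        fold_ev=tuple(float(e) for e in evs),
    )


def nested_specs(standardize: bool = True) -> list[DesignSpec]:
    """The full c+i+v model and all six reduced models."""
    base = ("contra_contrast", "ipsi_contrast", "reward_value")
    specs = [DesignSpec(base, standardize)]
    for r in (2, 1):
        for combo in itertools.combinations(base, r):
            specs.append(DesignSpec(combo, standardize))
    return specs


def compare_nested(
    trials: pd.DataFrame,
    responses: np.ndarray,
    hemisphere: str,
    k: int = 5,
    seed: int = 0,
    standardize: bool = True,
) -> pd.DataFrame:
    """Evaluate the full model and all 6 reduced models with shared folds.

    Returns a frame (one row per model) with the model label, number of
    regressors, held-out EV and AIC, sorted by EV descending.
    """
    folds = _fold_indices(len(trials), k, seed)
    rows = []
    for spec in nested_specs(standardize):
        X, y, dropped = build_design(trials, responses, spec, hemisphere)
        if X.shape[1] == 0:
            continue
        res = cv_explained_variance(X, y, k=k, seed=seed, folds=folds, spec=spec)
        rows.append(
            {
                "model": spec.label,
                "n_regressors": len(spec.regressors) - len(dropped),
                "explained_variance": res.explained_variance,
                "aic": res.aic,
                "k": k,
                "seed": seed,
            }
        )
    return (
        pd.DataFrame(rows)
        .sort_values("explained_variance", ascending=False)
        .reset_index(drop=True)
    )


def pupil_projection(
    pupil_xy: np.ndarray,
    frame_rate: float,
    smooth_window: float = 1.0,
) -> np.ndarray:
    """Reduce 2-D pupil centers to a z-scored 1-D gaze position.

    Median-filters each coordinate over ``smooth_window`` seconds,
    projects onto the principal axis of the 2-D point cloud, and
    z-scores.  The axis sign is fixed so the loading on x is positive.
    """
    xy = np.asarray(pupil_xy, dtype=float)
    if xy.ndim != 2 or xy.shape[1] != 2 or xy.shape[0] < 2:
        raise ValueError("pupil_xy must be (n_frames, 2) with n_frames >= 2")
    w = max(1, int(round(smooth_window * frame_rate)))
    if w % 2 == 0:
        w += 1
    sm_xy = np.column_stack([median_filter(xy[:, j], size=w, mode="nearest") for j in (0, 1)])
    centered = sm_xy - sm_xy.mean(axis=0)
    cov = np.cov(centered.T)
    evals, evecs = np.linalg.eigh(cov)
    axis = evecs[:, np.argmax(evals)]
    if axis[0] < 0:
        axis = -axis
    proj = centered @ axis
    sd = proj.std()
    if sd == 0:
        raise ValueError("pupil positions have zero variance")
    return (proj - proj.mean()) / sd


def pupil_by_trial(
    pupil_1d: np.ndarray,
    frame_rate: float,
    stimulus_times: np.ndarray,
    window: tuple[float, float] = (0.4, 0.8),
) -> np.ndarray:
    """Mean 1-D pupil position over the post-stimulus window, per trial."""
    pupil_1d = np.asarray(pupil_1d, dtype=float)
    out = np.empty(len(stimulus_times))
    for j, t0 in enumerate(np.asarray(stimulus_times, dtype=float)):
        lo = int(round((t0 + window[0]) * frame_rate))
        hi = int(round((t0 + window[1]) * frame_rate))
        if lo < 0 or hi > pupil_1d.size or hi <= lo:
            raise ValueError(f"pupil frames do not cover the window of trial {j}")
        out[j] = pupil_1d[lo:hi].mean()
    return out


def eye_control(
    trials: pd.DataFrame,
    responses: np.ndarray,
    pupil_trial_means: np.ndarray,
    hemisphere: str,
    standardize: bool = True,
) -> tuple[RegressionFit, pd.DataFrame]:
    """Fit R ~ c + i + p and return the fit plus the contrast-residualized
    responses paired with pupil position.

    The residual series is R - (b0 + b1 c + b2 i) from the 4-term fit,
    i.e. the fluorescence left unexplained by stimulus contrast, against
    which pupil position can be plotted or correlated.
    """
    spec = DesignSpec(
        ("contra_contrast", "ipsi_contrast", "pupil"), standardize=standardize
    )
    X, y, dropped = build_design(
        trials, responses, spec, hemisphere, pupil_by_trial=pupil_trial_means
    )
    fit = fit_ols(X, y)
    fit = RegressionFit(
        intercept=fit.intercept,
        slopes=fit.slopes,
        slope_se=fit.slope_se,
        n_trials=fit.n_trials,
        dropped=tuple(dropped),
        residuals=fit.residuals,
    )
    pred_contrast = np.full(len(y), fit.intercept)
    for name in ("contra_contrast", "ipsi_contrast"):
        if name in X.columns:
            pred_contrast = pred_contrast + fit.slopes[name] * X[name].to_numpy()
    resid = y - pred_contrast
    pairs = pd.DataFrame({"pupil": pupil_trial_means, "residual_response": resid})
    return fit, pairs
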