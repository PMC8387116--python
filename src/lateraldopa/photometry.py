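"""Two-channel photometry processing and the response-normalization hierarchy.

The correction and normalization chain is: fit the calcium-independent
control channel to the signal channel by least squares over the whole
session; DFF = (signal - fitted control) / fitted control; z-score the DFF
per session; align to task events; take windowed post-minus-pre responses;
divide by the session's peak averaged response to the highest-contrast
stimulus; finally average hemispheres within animal before averaging
across animals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


class ProcessingError(RuntimeError):
    """A processing step hit a degenerate input (constant channel,
    non-positive fitted baseline, empty alignment...)."""


@dataclass
class DffTrace:
    time: np.ndarray
    values: np.ndarray
    fit_slope: float
    fit_intercept: float

    @property
    def sampling_rate(self) -> float:
        return 1.0 / (self.time[1] - self.time[0])


@dataclass
class PeriEventMatrix:
    lags: np.ndarray  # seconds relative to event, strictly increasing
    matrix: np.ndarray  # retained events x lags
    event_label: str
    retained: np.ndarray  # indices (into the input event list) of retained events
    n_dropped: int


@dataclass
class ResponseVector:
    values: np.ndarray
    pre_window: tuple[float, float]
    post_window: tuple[float, float]
    normalization_peak: float = 1.0


def isosbestic_dff(signal: np.ndarray, control: np.ndarray, time: np.ndarray | None = None) -> DffTrace:
    """Ratiometric motion correction against the isosbestic control channel.

    An affine least-squares fit maps the control channel onto the signal
    channel over the whole session; the corrected trace is
    (signal - fitted control) / fitted control.  Shared bleaching and
    motion artifacts cancel; calcium transients, present only in the
    signal channel, survive.
    """
    signal = np.asarray(signal, dtype=float)
    control = np.asarray(control, dtype=float)
    if signal.shape != control.shape or signal.ndim != 1 or signal.size < 2:
        raise ValueError("signal and control must be equal-length 1-D arrays (n >= 2)")
    if np.ptp(control) == 0:
        raise ProcessingError("control channel is constant; isosbestic fit is degenerate")
    slope, intercept = np.polyfit(control, signal, 1)
    fitted = slope * control + intercept
    if np.any(fitted <= 0):
        raise ProcessingError("fitted control is non-positive at some samples")
    if time is None:
        time = np.arange(signal.size, dtype=float)
    return DffTrace(
        time=np.asarray(time, dtype=float),
        values=(signal - fitted) / fitted,
        fit_slope=float(slope),
        fit_intercept=float(intercept),
    )


def zscore_trace(values: np.ndarray) -> np.ndarray:
    """Session-wide z-score (mean 0, SD 1)."""
    values = np.asarray(values, dtype=float)
    sd = values.std()
    if sd == 0:
        raise ProcessingError("trace has zero variance; cannot z-score")
    return (values - values.mean()) / sd


def align_events(
    values: np.ndarray,
    time: np.ndarray,
    event_times: np.ndarray,
    window: tuple[float, float],
    event_label: str = "event",
) -> PeriEventMatrix:
    """Peri-event matrix by nearest-sample lookup on the uniform grid.

    Lags cover the half-open window [window[0], window[1]).  Events whose
    window falls outside the trace are dropped; their count is reported in
    ``n_dropped`` and retained indices in ``retained``.
    """
    w0, w1 = window
    if not w0 < w1:
        raise ValueError("window must be increasing")
    values = np.asarray(values, dtype=float)
    time = np.asarray(time, dtype=float)
    fs = 1.0 / (time[1] - time[0])
    off0 = int(round(w0 * fs))
    off1 = int(round(w1 * fs))  # exclusive
    lags = np.arange(off0, off1) / fs
    event_times = np.asarray(event_times, dtype=float)
    rows, retained = [], []
    n_dropped = 0
    for j, t0 in enumerate(event_times):
        if not np.isfinite(t0):
            n_dropped += 1
            continue
        i0 = int(round((t0 - time[0]) * fs))
        lo, hi = i0 + off0, i0 + off1
        if lo < 0 or hi > values.size:
            n_dropped += 1
            continue
        rows.append(values[lo:hi])
        retained.append(j)
    if not rows:
        raise ProcessingError(f"no events retained for label {event_label!r}")
    return PeriEventMatrix(
        lags=lags,
        matrix=np.vstack(rows),
        event_label=event_label,
        retained=np.asarray(retained),
        n_dropped=n_dropped,
    )


def window_response(
    peri: PeriEventMatrix,
    pre: tuple[float, float] = (-0.25, 0.0),
    post: tuple[float, float] = (0.4, 0.8),
) -> ResponseVector:
    """Per-trial scalar response: mean over the post window minus mean over
    the pre window (both half-open in lag)."""
    pre_mask = (peri.lags >= pre[0]) & (peri.lags < pre[1])
    post_mask = (peri.lags >= post[0]) & (peri.lags < post[1])
    if not pre_mask.any() or not post_mask.any():
        raise ProcessingError("pre or post window selects no lags")
    values = peri.matrix[:, post_mask].mean(axis=1) - peri.matrix[:, pre_mask].mean(axis=1)
    return ResponseVector(values=values, pre_window=pre, post_window=post)


def session_peak(
    peri_stim: PeriEventMatrix,
    contrasts: np.ndarray,
    peak_window: tuple[float, float] = (0.0, 1.5),
) -> float:
    """Peak of the trial-averaged stimulus-aligned trace over the
    highest-contrast trials, searched in lags (0, 1.5] by default."""
    contrasts = np.asarray(contrasts, dtype=float)[peri_stim.retained]
    cmax = contrasts.max()
    if cmax <= 0:
        raise ProcessingError("no nonzero-contrast trial available for peak normalization")
    sel = contrasts == cmax
    mean_trace = peri_stim.matrix[sel].mean(axis=0)
    lag_mask = (peri_stim.lags > peak_window[0]) & (peri_stim.lags <= peak_window[1])
    if not lag_mask.any():
        raise ProcessingError("peak window selects no lags")
    peak = float(mean_trace[lag_mask].max())
    if peak <= 0:
        raise ProcessingError(f"non-positive normalization peak ({peak:.3g}); session flagged")
    return peak


def peak_normalize(responses: ResponseVector, peak: float) -> ResponseVector:
    """Divide responses by the session's max-contrast peak response."""
    if peak <= 0:
        raise ProcessingError("normalization peak must be > 0")
    return ResponseVector(
        values=responses.values / peak,
        pre_window=responses.pre_window,
        post_window=responses.post_window,
        normalization_peak=peak,
    )


def aggregate_hierarchy(
    session_means: pd.DataFrame,
    value_col: str = "value",
    side_col: str = "stimulus_side",
    condition_cols: tuple[str, ...] = ("contrast",),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Hemisphere-then-animal averaging of per-session condition means.

    Input rows carry ``animal``, ``hemisphere``, a screen-side column and
    the condition columns.  Sides are relabeled contra/ipsi with respect
    to each recorded hemisphere; for bilateral animals the two hemispheres
    are averaged first; animals then contribute equally to the across-
    animal mean regardless of session counts.

    Returns ``(per_animal, across_animals)``.
    """
    required = {"animal", "hemisphere", side_col, value_col}
    missing = required - set(session_means.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    if session_means["hemisphere"].isna().any():
        raise ValueError("every session must carry a hemisphere tag")
    df = session_means.copy()

    def _lat(row):
        s, h = row[side_col], row["hemisphere"]
        if s in ("none", None) or (isinstance(s, float) and np.isnan(s)):
            return "none"
        return "contra" if s != h else "ipsi"

    df["laterality"] = df.apply(_lat, axis=1)
    keys = ["laterality", *condition_cols]
    per_hemi = (
        df.groupby(["animal", "hemisphere", *keys], as_index=False)[value_col].mean()
    )
    per_animal = per_hemi.groupby(["animal", *keys], as_index=False)[value_col].mean()
    across = per_animal.groupby(keys, as_index=False)[value_col].mean()
    return per_animal, across
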