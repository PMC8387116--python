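"""End-to-end orchestration: simulate -> process -> regress -> behavior -> TD.

Each stage writes plain files (CSV/JSON/HDF5) into the output directory so
stages can also be run independently from the CLI; the final JSON report
contains parameter snapshots, summary tables and SHA-256 hashes of every
text output, and is byte-identical across reruns with the same config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior as beh
from . import io as lio
from . import photometry as phot
from . import regression as reg
from .config import AnalysisConfig, PipelineConfig
from .observer import simulate_observer
from .synthesis import SyntheticSession, generate_session

logger = logging.getLogger(__name__)


def process_session(session: SyntheticSession, analysis: AnalysisConfig | None = None) -> dict:
    """Photometry chain for one session: DFF -> z-score -> align -> window
    responses -> peak normalization.

    Returns a dict with the corrected trace, the per-event peri-matrices,
    the session normalization peak, and the trial table augmented with
    ``resp_stim`` / ``resp_action`` / ``resp_outcome`` columns (NaN where
    the event is absent or its window fell off the trace).
    """
    analysis = analysis or AnalysisConfig()
    dff = phot.isosbestic_dff(session.signal_channel, session.control_channel, session.time)
    z = phot.zscore_trace(dff.values)
    trials = session.trials.copy()
    peri = {}
    for label, col in (("stimulus", "stimulus_time"), ("action", "action_time"), ("outcome", "outcome_time")):
        if col not in trials or trials[col].isna().all():
            continue
        try:
            peri[label] = phot.align_events(
                z, session.time, trials[col].to_numpy(dtype=float),
                analysis.align_window, event_label=label,
            )
        except phot.ProcessingError:
            continue
    peak = phot.session_peak(peri["stimulus"], trials["contrast"].to_numpy(), analysis.peak_window)
    for label, colname in (("stimulus", "resp_stim"), ("action", "resp_action"), ("outcome", "resp_outcome")):
        trials[colname] = np.nan
        if label in peri:
            resp = phot.window_response(peri[label], analysis.pre_window, analysis.post_window)
            norm = phot.peak_normalize(resp, peak)
            trials.loc[trials.index[peri[label].retained], colname] = norm.values
    return {"dff": dff, "zdff": z, "peri": peri, "peak": peak, "trials": trials}


def condition_means(trials: pd.DataFrame, animal: str, hemisphere: str) -> pd.DataFrame:
    """Per-session mean stimulus response by (side, contrast, reward size)."""
    df = trials.dropna(subset=["resp_stim"]).copy()
    out = (
        df.groupby(["stimulus_side", "contrast"], as_index=False)["resp_stim"].mean()
        .rename(columns={"resp_stim": "value"})
    )
    out.insert(0, "animal", animal)
    out.insert(1, "hemisphere", hemisphere)
    return out


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _session_seeds(base_seed: int, n: int, tag: int) -> list[int]:
    ss = np.random.SeedSequence([base_seed, tag])
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def run_pipeline(config: PipelineConfig, outdir: str | Path, write_h5: bool = False) -> dict:
    """Run the full analysis on freshly simulated VS and DMS sessions.

    Per profile and session: simulate, process photometry, compare the
    nested regression models; then aggregate condition means across the
    hemisphere/animal hierarchy, fit psychometric curves per reward block
    on the pooled choice trials, summarize the observer's TD errors, and
    (DMS) run the eye-movement control.  Writes CSV/JSON stage outputs and
    a deterministic ``report.json``; returns the report dict.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log = logging.getLogger("lateraldopa.pipeline")
    report: dict = {"config": config.to_dict(), "profiles": {}, "files": {}}
    fit_rows = []
    all_trials = []

    for p_idx, profile in enumerate(("VS", "DMS")):
        photo = dataclasses.replace(config.photometry, profile=profile)
        seeds = _session_seeds(config.seed, config.n_sessions, p_idx)
        comparisons, sess_means = [], []
        eye_fits = []
        for s_idx, seed in enumerate(seeds):
            hemi = "L" if s_idx % 2 == 0 else "R"
            photo_s = dataclasses.replace(photo, hemisphere=hemi)
            animal = f"{profile.lower()}_m{s_idx // 2}"
            session = generate_session(
                config.task, config.observer, photo_s, config.n_trials,
                seed=seed,
                pupil_coupling=config.pupil_coupling if profile == "DMS" else None,
                pupil_frame_rate=config.pupil_frame_rate,
                animal=animal,
            )
            log.info("simulated %s session %d (%s hemisphere, seed %d)", profile, s_idx, hemi, seed)
            proc = process_session(session, config.analysis)
            trials = proc["trials"]
            trials.insert(0, "session", s_idx)
            trials.insert(1, "animal", animal)
            trials.insert(2, "hemisphere", hemi)
            trials.insert(3, "profile", profile)
            all_trials.append(trials)

            ok = trials["resp_stim"].notna()
            comp = reg.compare_nested(
                trials[ok], trials.loc[ok, "resp_stim"].to_numpy(), hemi,
                k=config.analysis.cv_folds, seed=seed,
            )
            comp.insert(0, "session", s_idx)
            comparisons.append(comp)
            full_spec = reg.DesignSpec(("contra_contrast", "ipsi_contrast", "reward_value"))
            X, y, _ = reg.build_design(trials[ok], trials.loc[ok, "resp_stim"].to_numpy(), full_spec, hemi)
            fit = reg.fit_ols(X, y)
            fit_rows.append(
                {
                    "profile": profile, "session": s_idx, "model": "civ",
                    **{f"beta_{k}": v for k, v in fit.slopes.items()},
                    **{f"se_{k}": v for k, v in fit.slope_se.items()},
                    "n_trials": fit.n_trials, "seed": seed,
                }
            )
            sess_means.append(condition_means(trials, animal, hemi))

            if profile == "DMS" and session.pupil_xy is not None:
                p1 = reg.pupil_projection(session.pupil_xy, config.pupil_frame_rate)
                ptrial = reg.pupil_by_trial(
                    p1, config.pupil_frame_rate,
                    trials.loc[ok, "stimulus_time"].to_numpy(),
                    window=config.analysis.post_window,
                )
                efit, _ = reg.eye_control(trials[ok], trials.loc[ok, "resp_stim"].to_numpy(), ptrial, hemi)
                eye_fits.append(
                    {
                        "session": s_idx,
                        "pupil_slope": efit.slopes.get("pupil", np.nan),
                        "pupil_se": efit.slope_se.get("pupil", np.nan),
                        "contra_slope": efit.slopes.get("contra_contrast", np.nan),
                        "contra_se": efit.slope_se.get("contra_contrast", np.nan),
                    }
                )
            if write_h5:
                lio.write_session_h5(session, outdir / f"session_{profile}_{s_idx}.h5", photo_s)

        comp_all = pd.concat(comparisons, ignore_index=True)
        mean_ev = comp_all.groupby("model")["explained_variance"].mean().sort_values(ascending=False)
        per_animal, across = phot.aggregate_hierarchy(
            pd.concat(sess_means, ignore_index=True)
        )
        report["profiles"][profile] = {
            "model_comparison": {m: float(v) for m, v in mean_ev.items()},
            "best_model": str(mean_ev.index[0]),
            "condition_means": across.to_dict(orient="records"),
        }
        if eye_fits:
            report["profiles"][profile]["eye_control"] = eye_fits
        comp_all.to_csv(outdir / f"model_comparison_{profile}.csv", index=False)

    trials_all = pd.concat(all_trials, ignore_index=True)
    lio.write_trials_csv(trials_all, outdir / "trials.csv")
    pd.DataFrame(fit_rows).to_csv(outdir / "regression_fits.csv", index=False)

    # behavior: pooled choice trials across profiles (same task/observer)
    if config.task.mode == "choice":
        bres = beh.analyze_behavior(trials_all)
        bres["table"].to_csv(outdir / "psychometric.csv", index=False)
        report["behavior"] = {
            "fits": {
                side: dataclasses.asdict(fit) for side, fit in bres["fits"].items()
            },
        }
        if "reward_shift" in bres:
            report["behavior"]["reward_shift"] = float(bres["reward_shift"])

        # TD summaries from the generating observer's recorded internals
        ch = trials_all[trials_all["choice"].isin(["L", "R"])]
        td_summary = (
            ch.groupby(["contrast", "correct"], as_index=False)[["delta_stim", "delta_outcome"]]
            .mean()
        )
        report["td_model"] = {
            "mean_delta_outcome": float(ch["delta_outcome"].mean()),
            "by_contrast_and_accuracy": td_summary.to_dict(orient="records"),
        }
        td_out = simulate_observer(trials_all, config.observer, seed=config.seed)
        td_out.to_csv(outdir / "td_simulation.csv", index=False)

    for f in sorted(outdir.glob("*.csv")):
        report["files"][f.name] = _sha256(f)
    lio.write_json(report, outdir / "report.json")
    return report
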