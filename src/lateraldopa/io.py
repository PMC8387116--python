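"""Plain-file persistence: trial CSV tables and HDF5 trace containers."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .config import PhotometryConfig
from .synthesis import SyntheticSession


def write_trials_csv(trials: pd.DataFrame, path: str | Path) -> None:
    """One header row, one row per trial; absent values as empty cells."""
    trials.to_csv(path, index=False)


def read_trials_csv(path: str | Path) -> pd.DataFrame:
    trials = pd.read_csv(path)
    for col in ("stimulus_side", "choice", "large_reward_side"):
        if col in trials:
            trials[col] = trials[col].fillna("none")
    return trials


def write_session_h5(session: SyntheticSession, path: str | Path, photo: PhotometryConfig | None = None) -> None:
    """Datasets: time, signal, control, truth_dff, truth_amplitudes,
    pupil_xy (optional); attributes: seed, animal, hemisphere, profile and
    a JSON config snapshot."""
    with h5py.File(path, "w") as f:
        f.create_dataset("time", data=session.time)
        f.create_dataset("signal", data=session.signal_channel)
        f.create_dataset("control", data=session.control_channel)
        f.create_dataset("truth_dff", data=session.truth_dff)
        f.create_dataset("truth_amplitudes", data=session.truth_amplitudes.to_numpy())
        f["truth_amplitudes"].attrs["columns"] = json.dumps(
            list(session.truth_amplitudes.columns)
        )
        if session.pupil_xy is not None:
            f.create_dataset("pupil_xy", data=session.pupil_xy)
            f["pupil_xy"].attrs["frame_rate"] = session.pupil_frame_rate or 30.0
        f.attrs["seed"] = session.seed
        f.attrs["animal"] = session.animal
        f.attrs["hemisphere"] = session.hemisphere
        f.attrs["profile"] = session.profile
        if photo is not None:
            f.attrs["photometry_config"] = json.dumps(asdict(photo))


def read_session_h5(path: str | Path, trials: pd.DataFrame | None = None) -> SyntheticSession:
    with h5py.File(path, "r") as f:
        amps = pd.DataFrame(
            f["truth_amplitudes"][()],
            columns=json.loads(f["truth_amplitudes"].attrs["columns"]),
        )
        pupil = f["pupil_xy"][()] if "pupil_xy" in f else None
        frame_rate = f["pupil_xy"].attrs.get("frame_rate") if "pupil_xy" in f else None
        session = SyntheticSession(
            trials=trials if trials is not None else pd.DataFrame(),
            time=f["time"][()],
            signal_channel=f["signal"][()],
            control_channel=f["control"][()],
            truth_dff=f["truth_dff"][()],
            truth_amplitudes=amps,
            seed=int(f.attrs["seed"]),
            pupil_xy=pupil,
            pupil_frame_rate=float(frame_rate) if frame_rate is not None else None,
            animal=str(f.attrs.get("animal", "m0")),
            hemisphere=str(f.attrs.get("hemisphere", "L")),
            profile=str(f.attrs.get("profile", "VS")),
        )
    return session


def write_json(obj, path: str | Path) -> None:
    """Deterministic JSON: sorted keys, fixed float repr, trailing newline."""

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=default) + "\n")
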