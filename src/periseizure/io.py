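"""Readers and writers for the package's plain-text interchange formats.

All formats are CSV with a header row:

* EEG trace:       ``time_s, eeg_uV``
* EEG events:      ``onset_s, label, stim_hz``
* Photometry:      ``time_s, f465, f405``
* Hypnogram:       ``epoch_index, state``
* Design matrix:   ``id, pre_mean, during_mean, seizure_power``
* Seizure outcomes:``session_id, provoked, duration_s, band_power, stim_hz``

EDF reading is supported through :mod:`mne` when it is installed; CSV is
the canonical format.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .eeg import EEGRecording
from .errors import PeriSeizureError
from .metrics import Hypnogram, SeizureOutcome
from .photometry import PhotometryRecording

__all__ = [
    "read_eeg_csv",
    "write_eeg_csv",
    "read_events_csv",
    "write_events_csv",
    "read_eeg_edf",
    "read_photometry_csv",
    "write_photometry_csv",
    "read_hypnogram_csv",
    "write_hypnogram_csv",
    "read_design_matrix_csv",
    "write_design_matrix_csv",
    "write_outcomes_csv",
]


def _require_columns(df: pd.DataFrame, cols: list[str], path: Path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise PeriSeizureError(f"{path}: missing columns {missing}")


def read_eeg_csv(path: str | Path, events: list | None = None) -> EEGRecording:
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, ["time_s", "eeg_uV"], path)
    t = df["time_s"].to_numpy(float)
    if len(t) < 2:
        raise PeriSeizureError(f"{path}: need at least two samples")
    dt = np.diff(t)
    if np.ptp(dt) > 1e-6:
        raise PeriSeizureError(f"{path}: time grid is not uniform")
    fs = 1.0 / float(np.mean(dt))
    return EEGRecording(df["eeg_uV"].to_numpy(float), fs=fs, events=events or [])


def write_eeg_csv(rec: EEGRecording, path: str | Path) -> None:
    pd.DataFrame({"time_s": rec.time_s, "eeg_uV": rec.samples}).to_csv(
        path, index=False
    )


def read_events_csv(path: str | Path) -> list[tuple[float, str, float]]:
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, ["onset_s", "label", "stim_hz"], path)
    return [
        (float(r.onset_s), str(r.label), float(r.stim_hz)) for r in df.itertuples()
    ]


def write_events_csv(events: list[tuple[float, str, float]], path: str | Path) -> None:
    pd.DataFrame(events, columns=["onset_s", "label", "stim_hz"]).to_csv(
        path, index=False
    )


def read_eeg_edf(path: str | Path, channel: int | str = 0) -> EEGRecording:
    """Read one channel of an EDF file (requires the optional mne package)."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise PeriSeizureError(
            "EDF reading requires the 'mne' package; use the CSV format otherwise"
        ) from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    picks = [channel] if isinstance(channel, str) else [raw.ch_names[channel]]
    data = raw.get_data(picks=picks)[0] * 1e6  # volts -> microvolts
    return EEGRecording(samples=data, fs=float(raw.info["sfreq"]))


def read_photometry_csv(
    path: str | Path, induction_s: float, fs: float | None = None
) -> PhotometryRecording:
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, ["time_s", "f465", "f405"], path)
    t = df["time_s"].to_numpy(float)
    if fs is None:
        if len(t) < 2:
            raise PeriSeizureError(f"{path}: need at least two samples")
        fs = 1.0 / float(np.mean(np.diff(t)))
    return PhotometryRecording(
        time_s=t,
        f465=df["f465"].to_numpy(float),
        f405=df["f405"].to_numpy(float),
        fs=fs,
        induction_s=induction_s,
    )


def write_photometry_csv(rec: PhotometryRecording, path: str | Path) -> None:
    pd.DataFrame(
        {"time_s": rec.time_s, "f465": rec.f465, "f405": rec.f405}
    ).to_csv(path, index=False)


def read_hypnogram_csv(path: str | Path, epoch_s: float = 5.0) -> Hypnogram:
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, ["epoch_index", "state"], path)
    df = df.sort_values("epoch_index")
    return Hypnogram(states=[str(s) for s in df["state"]], epoch_s=epoch_s)


def write_hypnogram_csv(h: Hypnogram, path: str | Path) -> None:
    pd.DataFrame(
        {"epoch_index": range(len(h.states)), "state": h.states}
    ).to_csv(path, index=False)


def read_design_matrix_csv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, ["id", "pre_mean", "during_mean", "seizure_power"], path)
    if df[["pre_mean", "during_mean", "seizure_power"]].isna().any().any():
        raise PeriSeizureError(f"{path}: design matrix contains missing values")
    return df


def write_design_matrix_csv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def write_outcomes_csv(
    outcomes: list[SeizureOutcome], ids: list, path: str | Path
) -> None:
    pd.DataFrame(
        {
            "session_id": ids,
            "provoked": [o.provoked for o in outcomes],
            "duration_s": [o.duration_s for o in outcomes],
            "band_power": [o.band_power for o in outcomes],
            "stim_hz": [o.stim_hz for o in outcomes],
        }
    ).to_csv(path, index=False)
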