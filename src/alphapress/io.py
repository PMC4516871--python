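"""Session persistence: CSV trial tables and MNE-backed signal files.

The trial table is a tidy CSV, one row per trial, with click times stored
as semicolon-joined lists per ear. Epoched signals are written as MNE
Epochs FIF files (EEG/EMG scaled to volts, gaze kept as misc channels in
degrees) with the per-trial alignment events carried in the epochs
metadata. Real recordings in EDF (continuous, with the four event types as
annotations) are read through MNE's built-in EDF reader and epoched here.
"""

from __future__ import annotations

from pathlib import Path

import mne
import numpy as np
import pandas as pd

from .simulate import (
    ALL_CHANNELS,
    EEG_CHANNELS,
    EMG_CHANNELS,
    EPOCH_TMAX,
    EPOCH_TMIN,
    GAZE_CHANNELS,
    EpochedRecording,
    SessionResult,
    TrialRecord,
)
from .stimulus import ClickStimulus

__all__ = [
    "write_trial_table",
    "read_trial_table",
    "trials_from_frame",
    "write_epochs_fif",
    "read_epochs_fif",
    "read_epochs_edf",
]

EVENT_COLUMNS = ("trial_index", "stim_onset", "go_cue", "movement_onset", "movement_cessation")

_UV = 1e-6  # FIF stores volts; the package works in μV


def write_trial_table(session: SessionResult | pd.DataFrame, path: str | Path) -> Path:
    """Write the tidy trial table CSV."""
    frame = session.trial_frame() if isinstance(session, SessionResult) else session
    path = Path(path)
    frame.to_csv(path, index=False)
    return path


def read_trial_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, keep_default_na=False, na_values=[])


def _parse_times(cell) -> np.ndarray:
    if isinstance(cell, float) and np.isnan(cell):
        return np.array([])
    s = str(cell).strip()
    if not s:
        return np.array([])
    return np.array([float(x) for x in s.split(";")])


def trials_from_frame(frame: pd.DataFrame) -> list[TrialRecord]:
    """Rebuild trial records (including stimuli) from a trial table."""
    trials = []
    for _, row in frame.iterrows():
        stim = ClickStimulus(
            left_times=_parse_times(row["left_times"]),
            right_times=_parse_times(row["right_times"]),
            omega=int(row["omega"]),
            target_e=float(row["target_e"]),
            beta_at_generation=float(row["beta"]),
        )
        trials.append(
            TrialRecord(
                index=int(row["trial"]),
                stimulus=stim,
                dv_end=float(row["dv_end"]),
                choice=str(row["choice"]),
                correct=bool(row["correct"]) if not isinstance(row["correct"], str) else row["correct"] == "True",
                confidence=str(row["confidence"]),
                rt_ms=float(row["rt_ms"]),
                valid=bool(row["valid"]) if not isinstance(row["valid"], str) else row["valid"] == "True",
                invalid_reason=str(row["invalid_reason"]),
                feedback_points=int(row["feedback_points"]),
                beta=float(row["beta"]),
                subject_id=str(row["subject"]),
            )
        )
    return trials


def _channel_types(ch_names) -> list[str]:
    return [
        "eeg" if c in EEG_CHANNELS else ("emg" if c in EMG_CHANNELS else "misc")
        for c in ch_names
    ]


def write_epochs_fif(recording: EpochedRecording, path: str | Path) -> Path:
    """Write an EpochedRecording as an MNE Epochs FIF file (``*-epo.fif``)."""
    path = Path(path)
    types = _channel_types(recording.ch_names)
    info = mne.create_info(list(recording.ch_names), recording.sfreq, types)
    data = recording.data.copy()
    phys = [t in ("eeg", "emg") for t in types]
    data[:, phys, :] *= _UV
    n = data.shape[0]
    events = np.column_stack([np.arange(n) * data.shape[2], np.zeros(n, int), np.ones(n, int)])
    epochs = mne.EpochsArray(
        data, info, events=events, tmin=recording.tmin, verbose="error"
    )
    if recording.events is not None:
        epochs.metadata = recording.events.reset_index(drop=True)
    epochs.save(path, overwrite=True, verbose="error")
    return path


def read_epochs_fif(path: str | Path) -> EpochedRecording:
    epochs = mne.read_epochs(Path(path), preload=True, verbose="error")
    _validate_channels(epochs.ch_names)
    data = epochs.get_data(verbose="error").copy()
    types = epochs.get_channel_types()
    phys = [t in ("eeg", "emg") for t in types]
    data[:, phys, :] /= _UV
    meta = epochs.metadata
    events = meta.reset_index(drop=True) if meta is not None else None
    return EpochedRecording(
        data=data,
        ch_names=tuple(epochs.ch_names),
        sfreq=float(epochs.info["sfreq"]),
        tmin=float(epochs.tmin),
        events=events,
    )


def _validate_channels(ch_names) -> None:
    missing = [c for c in EEG_CHANNELS if c not in ch_names]
    if missing:
        raise ValueError(f"recording is missing required EEG channels: {missing}")


def read_epochs_edf(
    path: str | Path, tmin: float = EPOCH_TMIN, tmax: float = EPOCH_TMAX
) -> EpochedRecording:
    """Epoch a continuous EDF recording around its stimulus-onset annotations.

    The file must carry the 16-channel montage and annotations named
    stim_onset / go_cue / movement_onset / movement_cessation; within each
    trial the four events must appear in that order, else an error is
    raised rather than silently reordering.
    """
    raw = mne.io.read_raw_edf(Path(path), preload=True, verbose="error")
    _validate_channels(raw.ch_names)
    ann = raw.annotations
    events: dict[str, list[float]] = {k: [] for k in EVENT_COLUMNS[1:]}
    for onset, desc in zip(ann.onset, ann.description):
        if desc in events:
            events[desc].append(float(onset))
    n_trials = len(events["stim_onset"])
    if n_trials == 0:
        raise ValueError("no stim_onset annotations found")
    for key in EVENT_COLUMNS[2:]:
        if len(events[key]) != n_trials:
            raise ValueError(f"annotation count mismatch for {key}")
    for i in range(n_trials):
        seq = [events[k][i] for k in EVENT_COLUMNS[1:]]
        if sorted(seq) != seq:
            raise ValueError(f"trial {i}: annotations out of order {seq}")

    sfreq = float(raw.info["sfreq"])
    data = raw.get_data()
    n_samples = int(round((tmax - tmin) * sfreq))
    mats = []
    for onset in events["stim_onset"]:
        start = int(round((onset + tmin) * sfreq))
        if start < 0 or start + n_samples > data.shape[1]:
            raise ValueError("epoch extends beyond the recording")
        mats.append(data[:, start : start + n_samples])
    arr = np.stack(mats)
    # EDF voltage channels arrive in volts via MNE; convert to μV
    ch_names = tuple(raw.ch_names)
    types = ["eeg" if c in EEG_CHANNELS else ("emg" if c in EMG_CHANNELS else "misc") for c in ch_names]
    phys = [t in ("eeg", "emg") for t in types]
    arr[:, phys, :] /= _UV
    meta = pd.DataFrame(
        {
            "trial_index": np.arange(n_trials),
            "stim_onset": 0.0,
            "go_cue": np.array(events["go_cue"]) - np.array(events["stim_onset"]),
            "movement_onset": np.array(events["movement_onset"]) - np.array(events["stim_onset"]),
            "movement_cessation": np.array(events["movement_cessation"])
            - np.array(events["stim_onset"]),
        }
    )
    return EpochedRecording(data=arr, ch_names=ch_names, sfreq=sfreq, tmin=tmin, events=meta)
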