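"""Preprocessing and spectral estimation for epoched multichannel signals.

Implements the analysis chain applied to each epoch: common average
re-referencing over the EEG montage, amplitude-threshold artifact rejection
after slow-drift removal, zero-phase alpha-band (8-12 Hz) filtering,
mean-squared power in sliding windows (300 ms / 30 ms step by default), and
autoregressive power spectral densities by Burg's method (order 15) on a
1-80 Hz grid for time-frequency maps. EMG power uses the same windowing
after a 20-100 Hz band-pass.

"Power" throughout is the mean squared amplitude of the (filtered) signal in
a window, in μV²; window timestamps are window centers relative to the
epoch's alignment event.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.signal

from .simulate import EEG_CHANNELS, EpochedRecording, SFREQ

__all__ = [
    "PowerSeries",
    "TFMap",
    "car_rereference",
    "reject_artifact_trials",
    "bandpass_alpha",
    "bandpass_emg",
    "sliding_power",
    "burg_ar",
    "burg_psd",
    "time_frequency_map",
    "emg_power",
    "alpha_modulation",
]

#: PSD frequency grid, Hz (inclusive, 1 Hz spacing).
TF_FREQS = np.arange(1.0, 81.0)

# Elliptic band-pass designs. Each filter is applied forward and backward
# (zero net phase), so the per-pass stopband attenuation of 41 dB yields
# > 80 dB total at the stated stopband edges; 0.1 dB per-pass ripple keeps
# passband amplitude within ~2.5% after both passes.
def _ellip_bandpass(wp, ws, fs):
    order, wn = scipy.signal.ellipord(wp, ws, gpass=0.1, gstop=41.0, fs=fs)
    return scipy.signal.ellip(order, 0.1, 41.0, wn, btype="bandpass", fs=fs, output="sos")


@dataclass(frozen=True)
class PowerSeries:
    """Sliding-window band power for a set of trials.

    ``values`` has shape (n_trials, n_windows) — or (n_trials, n_channels,
    n_windows) when per-channel — in μV²; ``window_centers`` are seconds
    relative to the alignment event.
    """

    window_centers: np.ndarray
    values: np.ndarray
    window_ms: float
    step_ms: float
    channel_averaged: bool = True

    def __post_init__(self) -> None:
        if np.any(self.values < 0):
            raise ValueError("power values must be non-negative")
        if len(self.window_centers) > 1 and np.any(np.diff(self.window_centers) <= 0):
            raise ValueError("window centers must be strictly increasing")


@dataclass(frozen=True)
class TFMap:
    """Time-frequency power map: (n_trials, n_freqs, n_windows), μV²/Hz."""

    frequencies: np.ndarray
    window_centers: np.ndarray
    power: np.ndarray

    def band_mean(self, lo: float, hi: float) -> np.ndarray:
        """(n_trials, n_windows) mean power over frequencies in [lo, hi]."""
        mask = (self.frequencies >= lo) & (self.frequencies <= hi)
        return self.power[:, mask, :].mean(axis=1)


def car_rereference(epochs: np.ndarray, eeg_indices: list[int] | None = None) -> np.ndarray:
    """Common average reference: subtract the across-EEG-channel mean per sample.

    ``epochs`` is (..., n_channels, n_samples); only the channels named in
    ``eeg_indices`` (default: all) enter the average and are re-referenced,
    so EMG/gaze rows pass through untouched.
    """
    epochs = np.asarray(epochs, dtype=float)
    if eeg_indices is None:
        eeg_indices = list(range(epochs.shape[-2]))
    if len(eeg_indices) < 2:
        raise ValueError("CAR needs at least 2 EEG channels")
    out = epochs.copy()
    eeg = out[..., eeg_indices, :]
    out[..., eeg_indices, :] = eeg - eeg.mean(axis=-2, keepdims=True)
    return out


def reject_artifact_trials(
    recording: EpochedRecording,
    threshold_uv: float = 100.0,
    highpass_hz: float = 0.05,
    stim_window: tuple[float, float] = (0.0, 1.0),
) -> tuple[EpochedRecording, float]:
    """Drop trials whose EEG exceeds ±threshold during the stimulus period.

    Each EEG channel is first high-passed (2nd-order Butterworth at
    ``highpass_hz``, causal recursive, initialized at steady state on the
    first sample so the corner period — far longer than the epoch — does
    not produce startup transients) to remove slow drifts; a trial is
    removed when any stimulus-period sample on any EEG channel strictly
    exceeds +threshold or falls strictly below −threshold (samples exactly
    at the bound are kept). Returns the kept recording and the removed
    fraction.
    """
    if threshold_uv <= 0:
        raise ValueError("threshold must be positive")
    eeg_idx = recording.eeg_indices
    sos = scipy.signal.butter(2, highpass_hz, btype="highpass", fs=recording.sfreq, output="sos")
    eeg = recording.data[:, eeg_idx, :]
    zi = scipy.signal.sosfilt_zi(sos)  # (n_sections, 2)
    zi_full = zi[:, None, None, :] * eeg[None, :, :, 0, None]
    filtered, _ = scipy.signal.sosfilt(sos, eeg, axis=-1, zi=zi_full)
    t = recording.times
    in_stim = (t >= stim_window[0]) & (t <= stim_window[1])
    bad = np.any(np.abs(filtered[..., in_stim]) > threshold_uv, axis=(1, 2))
    kept = recording.subset(~bad)
    return kept, float(bad.mean())


_ALPHA_SOS = _ellip_bandpass([8.0, 12.0], [7.0, 13.0], SFREQ)
_EMG_BAND_SOS = _ellip_bandpass([20.0, 100.0], [19.0, 105.0], SFREQ)


def _filtfilt(sos: np.ndarray, x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    min_len = 3 * (2 * sos.shape[0] + 1)
    if x.shape[-1] < min_len:
        raise ValueError(f"signal too short for zero-phase filtering (< {min_len} samples)")
    return scipy.signal.sosfiltfilt(sos, x, axis=-1)


def bandpass_alpha(x: np.ndarray, sfreq: float = SFREQ) -> np.ndarray:
    """Zero-phase alpha-band (8-12 Hz) filter; ≥80 dB at 7 and 13 Hz after both passes."""
    if sfreq < 64.0:
        raise ValueError("sample rate must be at least 64 Hz")
    sos = _ALPHA_SOS if sfreq == SFREQ else _ellip_bandpass([8.0, 12.0], [7.0, 13.0], sfreq)
    return _filtfilt(sos, x)


def bandpass_emg(x: np.ndarray, sfreq: float = SFREQ) -> np.ndarray:
    """Zero-phase 20-100 Hz band-pass; ≥80 dB at 19 and 105 Hz after both passes."""
    sos = _EMG_BAND_SOS if sfreq == SFREQ else _ellip_bandpass([20.0, 100.0], [19.0, 105.0], sfreq)
    return _filtfilt(sos, x)


def _window_params(n_samples: int, sfreq: float, window_ms: float, step_ms: float):
    w = int(round(window_ms / 1000.0 * sfreq))
    s = max(int(round(step_ms / 1000.0 * sfreq)), 1)
    if n_samples < w:
        raise ValueError("signal shorter than one analysis window")
    n_win = (n_samples - w) // s + 1
    return w, s, n_win


def sliding_power(
    x: np.ndarray,
    sfreq: float = SFREQ,
    window_ms: float = 300.0,
    step_ms: float = 30.0,
    tmin: float = 0.0,
    channel_averaged: bool | None = None,
) -> PowerSeries:
    """Mean squared amplitude in sliding windows.

    ``x`` is (..., n_samples); windows lie entirely inside the signal (no
    padding) and timestamps are window centers offset by ``tmin``, the time
    of the first sample.
    """
    x = np.asarray(x, dtype=float)
    w, s, n_win = _window_params(x.shape[-1], sfreq, window_ms, step_ms)
    starts = np.arange(n_win) * s
    sq = x**2
    csum = np.concatenate(
        [np.zeros(sq.shape[:-1] + (1,)), np.cumsum(sq, axis=-1)], axis=-1
    )
    values = (csum[..., starts + w] - csum[..., starts]) / w
    centers = tmin + (starts + (w - 1) / 2.0) / sfreq
    if channel_averaged is None:
        channel_averaged = values.ndim == 1 or values.ndim == 2
    return PowerSeries(
        window_centers=centers,
        values=values,
        window_ms=window_ms,
        step_ms=step_ms,
        channel_averaged=channel_averaged,
    )


def burg_ar(x: np.ndarray, order: int) -> tuple[np.ndarray, float]:
    """Burg's method: AR coefficients and driving-noise variance.

    Minimizes the summed forward and backward prediction error via the
    Levinson-style lattice recursion. Returns ``a`` (length order+1, a[0]=1,
    for the model x[n] + a[1] x[n-1] + ... = e[n]) and the residual
    variance.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n <= order:
        raise ValueError("window length must exceed the AR order")
    f = x.copy()  # forward prediction errors
    b = x.copy()  # backward prediction errors
    a = np.array([1.0])
    sigma2 = float(np.mean(x**2))
    for _ in range(order):
        ef = f[1:]
        eb = b[:-1]
        denom = np.dot(ef, ef) + np.dot(eb, eb)
        if denom <= 0.0:
            a = np.concatenate([a, np.zeros(order + 1 - a.size)])
            break
        k = -2.0 * np.dot(ef, eb) / denom
        a = np.concatenate([a, [0.0]]) + k * np.concatenate([[0.0], a[::-1]])
        sigma2 *= 1.0 - k * k
        f, b = ef + k * eb, eb + k * ef
    return a, sigma2


def burg_psd(
    x: np.ndarray,
    sfreq: float = SFREQ,
    order: int = 15,
    freqs: np.ndarray = TF_FREQS,
) -> np.ndarray:
    """Autoregressive PSD (Burg, default order 15) on a frequency grid.

    PSD(f) = σ² / (fs · |A(e^{-j2πf/fs})|²), a one-sided AR spectrum in
    μV²/Hz whose grid mass approximates the window variance.
    """
    a, sigma2 = burg_ar(x, order)
    z = np.exp(-2j * np.pi * np.outer(freqs, np.arange(len(a))) / sfreq)
    denom = np.abs(z @ a) ** 2
    psd = 2.0 * sigma2 / (sfreq * denom)
    return np.maximum(psd, 0.0)


def time_frequency_map(
    recording: EpochedRecording,
    channels: list[str] | None = None,
    window_ms: float = 300.0,
    step_ms: float = 30.0,
    order: int = 15,
    channel_average: bool = True,
) -> TFMap:
    """Per-trial Burg PSD in sliding windows over the chosen channels.

    Channel averaging is of per-channel power (computed first, averaged
    after). Assumes the recording has already been CAR re-referenced.
    """
    channels = channels or [c for c in EEG_CHANNELS if c in recording.ch_names]
    idx = [recording.ch_names.index(c) for c in channels]
    data = recording.data[:, idx, :]
    n_trials, n_ch, n_samples = data.shape
    w, s, n_win = _window_params(n_samples, recording.sfreq, window_ms, step_ms)
    starts = np.arange(n_win) * s
    centers = recording.tmin + (starts + (w - 1) / 2.0) / recording.sfreq

    power = np.empty((n_trials, n_ch, len(TF_FREQS), n_win))
    for i in range(n_trials):
        for c in range(n_ch):
            sig = data[i, c]
            for k, st in enumerate(starts):
                power[i, c, :, k] = burg_psd(sig[st : st + w], recording.sfreq, order)
    if channel_average:
        power = power.mean(axis=1)
    return TFMap(frequencies=TF_FREQS.copy(), window_centers=centers, power=power)


def emg_power(
    emg: np.ndarray,
    sfreq: float = SFREQ,
    window_ms: float = 300.0,
    step_ms: float = 30.0,
    tmin: float = 0.0,
) -> PowerSeries:
    """Band-limited (20-100 Hz) EMG power in the same windows as the EEG power."""
    return sliding_power(bandpass_emg(emg, sfreq), sfreq, window_ms, step_ms, tmin)


def alpha_modulation(power: PowerSeries, subject_mean_power: float) -> np.ndarray:
    """Relative power decrease ("modulation") versus the subject's mean power.

    modulation = (mean − power)/mean, so larger values mean a more
    desynchronized alpha band. Returned as a plain array shaped like
    ``power.values`` (dimensionless, may be negative).
    """
    if subject_mean_power <= 0:
        raise ValueError("subject mean power must be positive")
    return (subject_mean_power - power.values) / subject_mean_power
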