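"""Synthetic sessions: choice behavior, confidence reports, and multichannel epochs.

A simulated subject performs the click-discrimination task in closed loop
with the adaptive staircase: choices follow a logistic psychometric function
of the end-of-stimulus decision variable, reaction time falls linearly with
|DV|, and the binary confidence report thresholds |DV| with noise and a
sequential shift. Per valid trial a 20-channel epoch (16 EEG + 2 EMG + 2
gaze) is synthesized at 256 Hz: 1/f background plus a 10 Hz oscillation
whose stimulus-period envelope drop at left-posterior channels scales with
confidence, DV, and RT — the structure the downstream regressions and the
confidence decoder are meant to recover.

Nothing here is biophysical: epochs have the statistical shape of the
phenomena (desynchronization, pre-movement EMG burst, saccadic gaze ramp),
not a forward model of cortex.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.signal
import scipy.special

from .stimulus import (
    AdaptiveState,
    ClickStimulus,
    LikelihoodTable,
    build_stimulus_bank,
    compute_dv_trace,
    estimate_click_likelihoods,
    select_stimulus,
)

__all__ = [
    "EEG_CHANNELS",
    "EMG_CHANNELS",
    "GAZE_CHANNELS",
    "ALL_CHANNELS",
    "SFREQ",
    "EPOCH_TMIN",
    "EPOCH_TMAX",
    "SimulatedSubject",
    "TrialRecord",
    "EpochedRecording",
    "simulate_choice",
    "simulate_rt",
    "simulate_confidence",
    "compute_feedback_points",
    "synthesize_epoch",
    "run_session",
    "SessionResult",
]

EEG_CHANNELS = (
    "F3", "Fz", "F4", "T7", "C3", "Cz", "C4", "T8",
    "CP3", "CP4", "P3", "Pz", "P4", "PO7", "PO8", "Oz",
)
EMG_CHANNELS = ("EMG_FCR", "EMG_FDS")
GAZE_CHANNELS = ("GAZE_X", "GAZE_Y")
ALL_CHANNELS = EEG_CHANNELS + EMG_CHANNELS + GAZE_CHANNELS

SFREQ = 256.0
EPOCH_TMIN = -0.5
EPOCH_TMAX = 2.5
STIM_DURATION = 1.0  # s; go cue at stimulus offset

#: Relative alpha-envelope gain per EEG channel; the confidence-linked
#: desynchronization is strongest over left posterior cortex (P3, CP3),
#: attenuated elsewhere.
ALPHA_TOPOGRAPHY = {
    "P3": 1.0, "CP3": 1.0, "PO7": 0.55, "Pz": 0.5, "P4": 0.4, "CP4": 0.4,
    "PO8": 0.35, "Oz": 0.35,
}
_DEFAULT_ALPHA_GAIN = 0.25

_INVALID_REASONS = ("too_early", "too_late", "both", "wrong_saccade", "fixation_break")

# EMG carrier band (20-100 Hz), designed once for the fixed 256 Hz rate
_EMG_SOS = scipy.signal.butter(4, [20.0, 100.0], btype="bandpass", fs=SFREQ, output="sos")


@dataclass(frozen=True)
class SimulatedSubject:
    """Generative parameters of one simulated participant.

    Defaults are chosen so that, in closed loop with the staircase, the
    subject sits near 75% correct, reports "sure" on roughly 60% of trials
    with the sequential dependence seen behaviorally, and shows a posterior
    alpha desynchronization that carries confidence information beyond DV
    and RT.
    """

    subject_id: str = "S01"
    choice_slope: float = 1.2       # logistic sensitivity per DV unit
    lapse_rate: float = 0.02
    rt_intercept_ms: float = 640.0
    rt_slope_ms_per_dv: float = -40.0
    rt_noise_ms: float = 50.0
    confidence_threshold: float = 1.0   # |DV| units
    confidence_noise: float = 0.5
    sequential_confidence_shift: float = 0.12
    alpha_effect: float = 0.5       # fractional envelope drop at full drive
    alpha_base_uv: float = 20.0     # resting 10 Hz envelope amplitude, posterior
    noise_uv: float = 10.0          # 1/f background s.d. per EEG channel
    # weights of confidence / |DV| / speed in the desynchronization drive g
    desync_weights: tuple[float, float, float] = (0.5, 0.3, 0.2)
    emg_baseline_uv: float = 1.5
    emg_burst_uv: float = 15.0
    gaze_noise_deg: float = 0.2
    # rates of task errors independent of stimulus difficulty (premature
    # presses, lapses of attention); the RT window rule adds a small
    # difficulty-correlated tail on top of these
    p_too_early: float = 0.06
    p_too_late: float = 0.045
    p_fixation_break: float = 0.02
    p_both_effectors: float = 0.005
    p_wrong_saccade: float = 0.03

    def __post_init__(self) -> None:
        if not 0.0 <= self.lapse_rate <= 0.1:
            raise ValueError("lapse_rate must lie in [0, 0.1]")
        if not 0.0 <= self.alpha_effect <= 1.0:
            raise ValueError("alpha_effect must lie in [0, 1]")


@dataclass
class TrialRecord:
    """One simulated trial of the click-discrimination task."""

    index: int
    stimulus: ClickStimulus
    dv_end: float
    choice: str                # "button" | "saccade"
    correct: bool
    confidence: str            # "sure" | "unsure"
    rt_ms: float
    valid: bool
    invalid_reason: str        # one of _INVALID_REASONS or "none"
    feedback_points: int
    beta: float                # staircase sensitivity when the trial ran
    subject_id: str = "S01"

    def __post_init__(self) -> None:
        if self.valid and not 200.0 < self.rt_ms <= 800.0:
            raise ValueError("valid trials must have rt_ms in (200, 800]")
        if self.invalid_reason not in _INVALID_REASONS + ("none",):
            raise ValueError(f"unknown invalid_reason {self.invalid_reason!r}")


@dataclass
class EpochedRecording:
    """Per-trial signal matrices with shared channel layout and timing.

    ``data`` has shape (n_epochs, n_channels, n_samples) in μV (EEG/EMG) or
    degrees (gaze); ``events`` carries per-epoch alignment times in seconds
    relative to stimulus onset.
    """

    data: np.ndarray
    ch_names: tuple[str, ...] = ALL_CHANNELS
    sfreq: float = SFREQ
    tmin: float = EPOCH_TMIN
    events: pd.DataFrame | None = None   # columns: trial_index, stim_onset, go_cue, movement_onset, movement_cessation

    def __post_init__(self) -> None:
        if self.data.ndim != 3 or self.data.shape[1] != len(self.ch_names):
            raise ValueError("data must be (n_epochs, n_channels, n_samples)")
        if self.events is not None and len(self.events) != self.data.shape[0]:
            raise ValueError("events must have one row per epoch")

    @property
    def times(self) -> np.ndarray:
        return self.tmin + np.arange(self.data.shape[2]) / self.sfreq

    @property
    def eeg_indices(self) -> list[int]:
        return [self.ch_names.index(c) for c in EEG_CHANNELS if c in self.ch_names]

    def channel(self, name: str) -> np.ndarray:
        """(n_epochs, n_samples) view of one channel."""
        return self.data[:, self.ch_names.index(name), :]

    def subset(self, epoch_mask: np.ndarray) -> "EpochedRecording":
        ev = self.events.loc[np.asarray(epoch_mask)].reset_index(drop=True) if self.events is not None else None
        return EpochedRecording(self.data[np.asarray(epoch_mask)], self.ch_names, self.sfreq, self.tmin, ev)


def simulate_choice(dv_end: float, subject: SimulatedSubject, rng: np.random.Generator) -> str:
    """Draw the choice: P(button) = lapse/2 + (1 − lapse)·logistic(slope·DV)."""
    p_button = subject.lapse_rate / 2.0 + (1.0 - subject.lapse_rate) * _expit(
        subject.choice_slope * dv_end
    )
    return "button" if rng.uniform() < p_button else "saccade"


def simulate_rt(
    dv_end: float, subject: SimulatedSubject, rng: np.random.Generator
) -> tuple[float, str]:
    """Reaction time, linear and decreasing in |DV| plus Gaussian noise.

    Returns ``(rt_ms, reason)`` where reason is "none" for draws inside the
    valid (200, 800] ms response window, else "too_early" / "too_late".
    """
    rt = (
        subject.rt_intercept_ms
        + subject.rt_slope_ms_per_dv * abs(dv_end)
        + rng.normal(0.0, subject.rt_noise_ms)
    )
    if rt <= 200.0:
        return float(rt), "too_early"
    if rt > 800.0:
        return float(rt), "too_late"
    return float(rt), "none"


def simulate_confidence(
    dv_end: float,
    prev_confidence: str | None,
    subject: SimulatedSubject,
    rng: np.random.Generator,
) -> str:
    """Binary report: sure iff |DV| + noise + sequential shift clears the threshold."""
    shift = 0.0
    if prev_confidence == "sure":
        shift = subject.sequential_confidence_shift
    elif prev_confidence == "unsure":
        shift = -subject.sequential_confidence_shift
    z = abs(dv_end) + rng.normal(0.0, subject.confidence_noise) + shift
    return "sure" if z > subject.confidence_threshold else "unsure"


def compute_feedback_points(correct: bool, e: float, confidence: str) -> int:
    """Points: ±10 for correctness, ±10 for a calibrated confidence report.

    The report is calibrated when the trial was generated as difficult
    (|E| < 0.5) and the subject was unsure, or easy (|E| >= 0.5) and sure.
    """
    if not -1.0 < e < 1.0:
        raise ValueError("e must lie strictly in (-1, 1)")
    points = 10 if correct else -10
    easy = abs(e) >= 0.5
    calibrated = (easy and confidence == "sure") or (not easy and confidence == "unsure")
    return points + (10 if calibrated else -10)


def _expit(x: float) -> float:
    return float(scipy.special.expit(x))


def _pink_noise(rng: np.random.Generator, n_channels: int, n_samples: int, std: float) -> np.ndarray:
    """1/f-amplitude background noise, unit-normalized then scaled to ``std``."""
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / SFREQ)
    shaping = np.zeros_like(freqs)
    shaping[1:] = 1.0 / np.sqrt(freqs[1:])
    spec = (
        rng.normal(size=(n_channels, freqs.size)) + 1j * rng.normal(size=(n_channels, freqs.size))
    ) * shaping
    x = np.fft.irfft(spec, n=n_samples, axis=1)
    x /= x.std(axis=1, keepdims=True)
    return std * x


def _desync_drive(trial: TrialRecord, subject: SimulatedSubject) -> float:
    """g(confidence, DV, RT) ∈ [0, 1]: monotone weighted drive of the envelope drop."""
    w_conf, w_dv, w_rt = subject.desync_weights
    conf_term = 1.0 if trial.confidence == "sure" else 0.0
    dv_term = min(abs(trial.dv_end) / 3.0, 1.0)
    rt_term = float(np.clip((800.0 - trial.rt_ms) / 600.0, 0.0, 1.0))
    total = w_conf + w_dv + w_rt
    return (w_conf * conf_term + w_dv * dv_term + w_rt * rt_term) / total


def _depth_profile(
    t: np.ndarray, depth: float, movement_onset: float, choice: str, alpha_effect: float
) -> np.ndarray:
    """Fractional envelope drop over time: ramp in during the stimulus, hold,
    then (button trials) converge to a condition-independent pre-movement level."""
    profile = depth * np.clip((t - 0.3) / 0.3, 0.0, 1.0)
    if choice == "button":
        common = 0.8 * alpha_effect
        ramp = np.clip((t - (movement_onset - 0.1)) / 0.1, 0.0, 1.0)
        profile = profile * (1.0 - ramp) + common * ramp
        decay = np.clip((t - (movement_onset + 0.2)) / 0.4, 0.0, 1.0)
        profile = profile * (1.0 - decay)
    else:
        decay = np.clip((t - movement_onset) / 0.3, 0.0, 1.0)
        profile = profile * (1.0 - decay)
    return profile


def synthesize_epoch(
    trial: TrialRecord, subject: SimulatedSubject, rng: np.random.Generator
) -> np.ndarray:
    """Synthesize one (n_channels, n_samples) epoch for a valid trial.

    EEG channels: 1/f noise plus a 10 Hz oscillation whose envelope drops
    during the stimulus/pre-movement period by alpha_effect · g(confidence,
    DV, RT), scaled by the channel's posterior gain. EMG: band-limited noise
    with a burst from 150 ms before the button press until movement
    cessation (button trials only). Gaze: fixation noise, with a leftward
    ramp at movement onset on saccade trials.
    """
    if not trial.valid:
        raise ValueError("epochs are synthesized for valid trials only")
    n_samples = int(round((EPOCH_TMAX - EPOCH_TMIN) * SFREQ))
    t = EPOCH_TMIN + np.arange(n_samples) / SFREQ
    movement_onset = STIM_DURATION + trial.rt_ms / 1000.0
    movement_cessation = movement_onset + 0.2

    data = np.zeros((len(ALL_CHANNELS), n_samples))

    # --- EEG ---
    g = _desync_drive(trial, subject)
    depth = subject.alpha_effect * g
    profile = _depth_profile(t, depth, movement_onset, trial.choice, subject.alpha_effect)
    phase = rng.uniform(0.0, 2.0 * np.pi)
    carrier = np.sin(2.0 * np.pi * 10.0 * t + phase)
    n_eeg = len(EEG_CHANNELS)
    data[:n_eeg] = _pink_noise(rng, n_eeg, n_samples, subject.noise_uv)
    for i, ch in enumerate(EEG_CHANNELS):
        gain = ALPHA_TOPOGRAPHY.get(ch, _DEFAULT_ALPHA_GAIN)
        envelope = subject.alpha_base_uv * gain * (1.0 - profile)
        data[i] += envelope * carrier

    # --- EMG ---
    for j in range(len(EMG_CHANNELS)):
        idx = n_eeg + j
        raw = rng.normal(size=n_samples)
        band = scipy.signal.sosfiltfilt(_EMG_SOS, raw)
        band /= band.std()
        envelope = np.full(n_samples, subject.emg_baseline_uv)
        if trial.choice == "button":
            burst = np.clip((t - (movement_onset - 0.15)) / 0.15, 0.0, 1.0) * np.clip(
                (movement_cessation + 0.1 - t) / 0.1, 0.0, 1.0
            )
            envelope = envelope + subject.emg_burst_uv * np.clip(burst, 0.0, 1.0)
        data[idx] = envelope * band

    # --- gaze (degrees) ---
    gx = rng.normal(0.0, subject.gaze_noise_deg, size=n_samples)
    gy = rng.normal(0.0, subject.gaze_noise_deg, size=n_samples)
    if trial.choice == "saccade":
        ramp = np.clip((t - movement_onset) / 0.05, 0.0, 1.0)
        gx = gx - 15.0 * ramp
    data[n_eeg + len(EMG_CHANNELS)] = gx
    data[n_eeg + len(EMG_CHANNELS) + 1] = gy
    return data


@dataclass
class SessionResult:
    """Everything one simulated session produces."""

    subject: SimulatedSubject
    trials: list[TrialRecord]
    table: LikelihoodTable
    epochs: EpochedRecording | None
    beta_history: np.ndarray

    @property
    def valid_trials(self) -> list[TrialRecord]:
        return [tr for tr in self.trials if tr.valid]

    def trial_frame(self) -> pd.DataFrame:
        """Tidy trial table (one row per trial, click times as ;-joined lists)."""
        rows = []
        for tr in self.trials:
            s = tr.stimulus
            rows.append(
                {
                    "trial": tr.index,
                    "subject": tr.subject_id,
                    "omega": s.omega,
                    "c_r": s.c_r,
                    "c_l": s.c_l,
                    "target_e": s.target_e,
                    "beta": tr.beta,
                    "left_times": ";".join(f"{x:.6f}" for x in s.left_times),
                    "right_times": ";".join(f"{x:.6f}" for x in s.right_times),
                    "dv_end": tr.dv_end,
                    "choice": tr.choice,
                    "correct": tr.correct,
                    "confidence": tr.confidence,
                    "rt_ms": tr.rt_ms,
                    "valid": tr.valid,
                    "invalid_reason": tr.invalid_reason,
                    "feedback_points": tr.feedback_points,
                }
            )
        return pd.DataFrame(rows)


#: Provisional symmetric likelihoods used to drive the observer online; the
#: analysis-grade table is re-estimated from the realized session afterwards.
PROVISIONAL_TABLE = LikelihoodTable(p_right_given_button=0.6, p_right_given_saccade=0.4)


def run_session(
    n_trials: int,
    subject: SimulatedSubject | None = None,
    seed: int | np.random.Generator = 0,
    *,
    synthesize_signals: bool = True,
) -> SessionResult:
    """Simulate one closed-loop session.

    Per trial: draw E ~ U(−1, 1), pre-generate a 10-stimulus bank at the
    current β, present the nearest stimulus, let the subject choose/report,
    assign feedback points, and update β from accuracy over the last 20
    valid trials. After the loop the click likelihood table is re-estimated
    from the realized trials and every trial's ``dv_end`` is recomputed with
    it; epochs (valid trials only) are synthesized from the final records.
    Fully reproducible from ``seed``.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    subject = subject or SimulatedSubject()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    state = AdaptiveState()
    trials: list[TrialRecord] = []
    beta_history = np.empty(n_trials)
    prev_confidence: str | None = None

    for i in range(n_trials):
        beta_history[i] = state.beta
        bank = build_stimulus_bank(state.beta, rng)
        e = float(rng.uniform(-1.0, 1.0))
        stim = select_stimulus(e, bank, state.beta)
        stim = replace(stim, target_e=e)

        dv_online = compute_dv_trace(stim, PROVISIONAL_TABLE).dv_end
        choice = simulate_choice(dv_online, subject, rng)
        correct = (choice == "button" and stim.c_r > stim.c_l) or (
            choice == "saccade" and stim.c_l > stim.c_r
        )
        rt, reason = simulate_rt(dv_online, subject, rng)
        confidence = simulate_confidence(dv_online, prev_confidence, subject, rng)

        if reason == "none":
            u = rng.uniform()
            edges = np.cumsum(
                [
                    subject.p_too_early,
                    subject.p_too_late,
                    subject.p_fixation_break,
                    subject.p_both_effectors,
                    subject.p_wrong_saccade if choice == "saccade" else 0.0,
                ]
            )
            labels = ("too_early", "too_late", "fixation_break", "both", "wrong_saccade")
            hit = int(np.searchsorted(edges, u, side="right"))
            if hit < len(labels):
                reason = labels[hit]
        valid = reason == "none"

        feedback = compute_feedback_points(correct, e, confidence) if valid else 0
        trials.append(
            TrialRecord(
                index=i,
                stimulus=stim,
                dv_end=dv_online,
                choice=choice,
                correct=correct,
                confidence=confidence,
                rt_ms=rt,
                valid=valid,
                invalid_reason=reason,
                feedback_points=feedback,
                beta=state.beta,
                subject_id=subject.subject_id,
            )
        )
        if valid:
            prev_confidence = confidence
            state.record(correct)
            state.step()

    # analysis-grade DV: likelihoods estimated from the realized session
    valid = [tr for tr in trials if tr.valid]
    choices_seen = {tr.choice for tr in valid}
    if choices_seen == {"button", "saccade"}:
        table = estimate_click_likelihoods(valid)
    else:  # degenerate tiny session: keep the provisional table
        table = PROVISIONAL_TABLE
    for tr in trials:
        tr.dv_end = compute_dv_trace(tr.stimulus, table).dv_end

    epochs = None
    if synthesize_signals:
        mats = [synthesize_epoch(tr, subject, rng) for tr in valid]
        events = pd.DataFrame(
            {
                "trial_index": [tr.index for tr in valid],
                "stim_onset": 0.0,
                "go_cue": STIM_DURATION,
                "movement_onset": [STIM_DURATION + tr.rt_ms / 1000.0 for tr in valid],
                "movement_cessation": [STIM_DURATION + tr.rt_ms / 1000.0 + 0.2 for tr in valid],
            }
        )
        epochs = EpochedRecording(np.stack(mats), events=events)

    return SessionResult(
        subject=subject,
        trials=trials,
        table=table,
        epochs=epochs,
        beta_history=beta_history,
    )
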