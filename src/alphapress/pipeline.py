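"""End-to-end synthetic study: simulate, preprocess, analyze, decode.

`run_synthetic_study` ties the modules together: it simulates multi-subject
sessions in closed loop with the staircase, preprocesses the epochs (CAR +
artifact rejection), computes channel-averaged alpha power, fits the
per-window partial-effect regression to locate the confidence-significance
window, extracts the per-trial neural feature (window-averaged alpha
modulation), and evaluates the median-criterion confidence decoder with its
permutation null. Everything derives from one master seed; per-stage seeds
are spawned from it.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import classifier, regression, signals
from .simulate import (
    EEG_CHANNELS,
    EMG_CHANNELS,
    GAZE_CHANNELS,
    EpochedRecording,
    SessionResult,
    SimulatedSubject,
    run_session,
)
from .stimulus import compute_dv_trace

logger = logging.getLogger("alphapress")

__all__ = [
    "PipelineConfig",
    "alpha_power_series",
    "session_features",
    "run_synthetic_study",
    "load_real_session",
]

#: Fixed fallback feature window (s, relative to stimulus onset), used when
#: a session is too small for a stable significance run.
FALLBACK_WINDOW = (0.4, 1.0)


@dataclass
class PipelineConfig:
    """Settings of the synthetic study; all fields JSON/key-value serializable."""

    seed: int = 0
    n_subjects: int = 6
    n_trials: int = 250
    alpha_effect: float = 0.5
    window_ms: float = 300.0
    step_ms: float = 30.0
    artifact_threshold_uv: float = 100.0
    criterion: float = 0.55
    n_permutations: int = 200
    subject_jitter: float = 0.1
    output_dir: str = ""

    def to_file(self, path: str | Path) -> Path:
        path = Path(path)
        lines = [f"{k} = {v}" for k, v in dataclasses.asdict(self).items()]
        path.write_text("\n".join(lines) + "\n")
        return path

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        kwargs = {}
        types = {f.name: f.type for f in dataclasses.fields(cls)}
        casts = {"int": int, "float": float, "str": str}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key not in types:
                raise ValueError(f"unknown config key {key!r}")
            kwargs[key] = casts[str(types[key])](value)
        return cls(**kwargs)


def _spawn_subject(base: SimulatedSubject, i: int, jitter: float, rng: np.random.Generator) -> SimulatedSubject:
    """Per-subject parameter variation around the base observer."""
    return dataclasses.replace(
        base,
        subject_id=f"S{i + 1:02d}",
        alpha_effect=float(np.clip(base.alpha_effect + rng.uniform(-jitter, jitter), 0.0, 1.0)),
        confidence_threshold=base.confidence_threshold + rng.uniform(-jitter, jitter),
        rt_intercept_ms=base.rt_intercept_ms + rng.uniform(-30.0, 30.0) * (jitter > 0),
        alpha_base_uv=base.alpha_base_uv * (1.0 + rng.uniform(-jitter, jitter)),
    )


def alpha_power_series(
    recording: EpochedRecording, window_ms: float = 300.0, step_ms: float = 30.0
) -> signals.PowerSeries:
    """Channel-averaged alpha-band power per trial after CAR.

    Returns a PowerSeries with values (n_trials, n_windows): EEG channels
    are re-referenced, alpha-filtered, windowed per channel, then averaged
    over channels (power averaging after per-channel computation).
    """
    eeg_idx = recording.eeg_indices
    data = signals.car_rereference(recording.data, eeg_idx)[:, eeg_idx, :]
    filtered = signals.bandpass_alpha(data, recording.sfreq)
    per_channel = signals.sliding_power(
        filtered, recording.sfreq, window_ms, step_ms, tmin=recording.tmin
    )
    return signals.PowerSeries(
        window_centers=per_channel.window_centers,
        values=per_channel.values.mean(axis=1),
        window_ms=window_ms,
        step_ms=step_ms,
        channel_averaged=True,
    )


def _dynamic_regressors(
    session: SessionResult, recording: EpochedRecording, centers: np.ndarray
) -> dict[str, np.ndarray]:
    """Instantaneous DV, EMG power and gaze position at the window centers."""
    meta = recording.events
    by_index = {tr.index: tr for tr in session.trials}
    trials = [by_index[i] for i in meta["trial_index"]]

    dv = np.empty((len(trials), len(centers)))
    for r, tr in enumerate(trials):
        trace = compute_dv_trace(tr.stimulus, session.table)
        dv[r] = [trace.value_at(min(max(t, 0.0), 1.0)) for t in centers]

    emg = signals.emg_power(
        recording.channel(EMG_CHANNELS[0]), recording.sfreq, tmin=recording.tmin
    ).values

    gaze_sig = recording.channel(GAZE_CHANNELS[0])
    w = int(round(300.0 / 1000.0 * recording.sfreq))
    s = int(round(30.0 / 1000.0 * recording.sfreq))
    starts = np.arange(emg.shape[1]) * s
    gaze = np.stack([gaze_sig[:, st : st + w].mean(axis=1) for st in starts], axis=1)
    return {"dv": dv, "hand_emg": emg, "eye_pos": gaze}


def session_features(
    session: SessionResult,
    window: tuple[float, float] | None = None,
    window_ms: float = 300.0,
    step_ms: float = 30.0,
    artifact_threshold_uv: float = 100.0,
) -> pd.DataFrame:
    """Per-trial decoding features and covariates for one session.

    Preprocesses the session's epochs, computes channel-averaged alpha
    power, converts it to modulation against the session mean power, and
    averages it over the feature ``window`` (default: the fixed fallback
    window). Returns a tidy frame with one row per kept button/saccade
    trial: subject, trial_index, choice, confidence, correct, rt_ms,
    dv_end, neural (window-averaged alpha modulation), hand_emg, eye_pos.
    """
    if session.epochs is None:
        raise ValueError("session was simulated without signals")
    window = window or FALLBACK_WINDOW
    kept, removed = signals.reject_artifact_trials(session.epochs, artifact_threshold_uv)
    if removed > 0:
        logger.info("artifact rejection removed %.1f%% of trials", 100 * removed)
    power = alpha_power_series(kept, window_ms, step_ms)
    subject_mean = float(power.values.mean())
    modulation = signals.alpha_modulation(power, subject_mean)
    in_win = (power.window_centers >= window[0]) & (power.window_centers <= window[1])
    neural = modulation[:, in_win].mean(axis=1)

    emg = signals.emg_power(kept.channel(EMG_CHANNELS[0]), kept.sfreq, tmin=kept.tmin)
    emg_feat = emg.values[:, (emg.window_centers >= window[0]) & (emg.window_centers <= window[1])].mean(axis=1)
    t = kept.times
    gaze_mask = (t >= window[0]) & (t <= window[1])
    eye_feat = kept.channel(GAZE_CHANNELS[0])[:, gaze_mask].mean(axis=1)

    by_index = {tr.index: tr for tr in session.trials}
    rows = []
    for r, idx in enumerate(kept.events["trial_index"]):
        tr = by_index[int(idx)]
        rows.append(
            {
                "subject": tr.subject_id,
                "trial_index": tr.index,
                "choice": tr.choice,
                "confidence": tr.confidence,
                "correct": tr.correct,
                "rt_ms": tr.rt_ms,
                "dv_end": tr.dv_end,
                "neural": float(neural[r]),
                "hand_emg": float(emg_feat[r]),
                "eye_pos": float(eye_feat[r]),
            }
        )
    return pd.DataFrame(rows)


def collect_button_features(
    n_button: int,
    subject: SimulatedSubject | None = None,
    seed: int | np.random.Generator = 0,
    window: tuple[float, float] | None = None,
    session_trials: int = 400,
) -> pd.DataFrame:
    """Accumulate button-press trial features until ``n_button`` are available.

    Runs closed-loop sessions (with signals), extracts per-trial alpha
    modulation features, keeps the button-press rows, and returns exactly
    ``n_button`` of them. Used for decoder evaluations that need a fixed
    trial count.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    frames = []
    total = 0
    while total < n_button:
        session = run_session(session_trials, subject, rng)
        feats = session_features(session, window)
        btn = feats[feats["choice"] == "button"]
        frames.append(btn)
        total += len(btn)
    return pd.concat(frames, ignore_index=True).iloc[:n_button].reset_index(drop=True)


def _confidence_window(
    session: SessionResult,
    kept: EpochedRecording,
    power: signals.PowerSeries,
    step_ms: float,
) -> tuple[tuple[float, float], regression.EffectTrace | None]:
    """Locate the stimulus-period significance run of the confidence effect.

    Runs the partial-effect regression per window on button trials and takes
    the first ≥10-window run of p < 0.01 within the stimulus period; falls
    back to the fixed window when none exists or trials are too few.
    """
    meta = kept.events
    by_index = {tr.index: tr for tr in session.trials}
    trials = [by_index[int(i)] for i in meta["trial_index"]]
    button = np.array([tr.choice == "button" for tr in trials])
    if button.sum() < 40:
        return FALLBACK_WINDOW, None
    sub = kept.subset(button)
    sub_power = power.values[button]
    sub_trials = [t for t, b in zip(trials, button) if b]
    static = pd.DataFrame(
        {
            "confidence": [1.0 if t.confidence == "sure" else 0.0 for t in sub_trials],
            "rt": [t.rt_ms for t in sub_trials],
        }
    )
    # pre-stimulus windows carry a constant (zero) DV, which would make the
    # design rank deficient — regress over stimulus-period-and-later windows
    w_keep = power.window_centers >= 0.1
    centers = power.window_centers[w_keep]
    dynamic = {k: v[:, w_keep] for k, v in _dynamic_regressors(session, sub, power.window_centers).items()}
    trace = regression.effect_timecourse(sub_power[:, w_keep], centers, static, dynamic)
    runs = [
        r
        for r in trace.significance_runs("confidence", alpha=0.01, min_run=10)
        if r[0] >= 0.0 and r[0] <= 1.2
    ]
    if not runs:
        return FALLBACK_WINDOW, trace
    return (runs[0][0], min(runs[0][1], 1.2)), trace


def run_synthetic_study(config: PipelineConfig | None = None) -> dict:
    """Run the full synthetic study; returns a JSON-serializable report.

    Stages per subject: session simulation → artifact rejection + CAR →
    alpha power → confidence-window localization (partial-effect regression)
    → feature extraction → per-subject decoding with permutation null.
    Pooled analyses: behavioral statistics, channel significance map, and
    the mixed-effects confidence model.
    """
    config = config or PipelineConfig()
    master = np.random.default_rng(config.seed)
    subject_seeds = master.integers(0, 2**31 - 1, size=config.n_subjects)
    base = SimulatedSubject(alpha_effect=config.alpha_effect)

    features = []
    per_subject = []
    staircase_acc = []
    frames = []
    channel_rows = []
    for i, s_seed in enumerate(subject_seeds):
        rng = np.random.default_rng(s_seed)
        subject = _spawn_subject(base, i, config.subject_jitter, rng)
        session = run_session(config.n_trials, subject, rng)
        frames.append(session.trial_frame())
        valid = session.valid_trials
        staircase_acc.append(100.0 * np.mean([t.correct for t in valid]))

        kept, _ = signals.reject_artifact_trials(session.epochs, config.artifact_threshold_uv)
        power = alpha_power_series(kept, config.window_ms, config.step_ms)
        window, _trace = _confidence_window(session, kept, power, config.step_ms)
        feats = session_features(
            session, window, config.window_ms, config.step_ms, config.artifact_threshold_uv
        )
        features.append(feats)

        # per-channel window-averaged alpha power for the topography map
        eeg_idx = kept.eeg_indices
        car = signals.car_rereference(kept.data, eeg_idx)[:, eeg_idx, :]
        ch_power = signals.sliding_power(
            signals.bandpass_alpha(car, kept.sfreq), kept.sfreq,
            config.window_ms, config.step_ms, tmin=kept.tmin,
        )
        in_win = (ch_power.window_centers >= window[0]) & (ch_power.window_centers <= window[1])
        btn = feats["choice"] == "button"
        channel_rows.append(
            (
                ch_power.values[:, :, in_win].mean(axis=2)[btn.to_numpy()],
                (feats["confidence"] == "sure").to_numpy()[btn.to_numpy()].astype(float),
                feats["subject"].to_numpy()[btn.to_numpy()],
            )
        )

        btn_feats = feats[feats["choice"] == "button"]
        labels = btn_feats["confidence"].to_numpy()
        values = btn_feats["neural"].to_numpy()
        perm = classifier.permutation_test(
            values, labels, config.criterion, config.n_permutations,
            np.random.default_rng(s_seed + 1),
        )
        per_subject.append(
            {
                "subject": subject.subject_id,
                "window": list(window),
                "n_button_trials": int(len(btn_feats)),
                "accuracy": perm["observed"],
                "null_mean": perm["null_mean"],
                "p_value": perm["p_value"],
            }
        )
        logger.info("subject %s: decoding %.1f%% (p=%.3g)", subject.subject_id,
                    perm["observed"], perm["p_value"])

    all_feats = pd.concat(features, ignore_index=True)
    all_trials = pd.concat(frames, ignore_index=True)
    behavior = regression.behavioral_stats(
        all_trials[all_trials["valid"].astype(bool)].reset_index(drop=True)
    )

    ch_pow = np.vstack([c[0] for c in channel_rows])
    ch_conf = np.concatenate([c[1] for c in channel_rows])
    ch_subj = np.concatenate([c[2] for c in channel_rows])
    channel_map = regression.channel_significance_map(
        ch_pow, list(EEG_CHANNELS), ch_conf, ch_subj
    )

    btn = all_feats[all_feats["choice"] == "button"].reset_index(drop=True)
    conf_model = regression.fit_confidence_model(
        btn.assign(confidence=(btn["confidence"] == "sure").astype(float), rt=btn["rt_ms"]),
        predictors=("neural", "dv_end", "rt", "hand_emg", "eye_pos"),
    )

    report = {
        "config": dataclasses.asdict(config),
        "staircase": {
            "per_subject_accuracy": staircase_acc,
            "mean_accuracy": float(np.mean(staircase_acc)),
        },
        "behavior": behavior,
        "channel_map": channel_map.to_dict(orient="records"),
        "confidence_model": {
            "weights": conf_model["weights"].to_dict(),
            "pvalues": conf_model["pvalues"].to_dict(),
            "method": conf_model["method"],
        },
        "classifier": {
            "criterion": config.criterion,
            "per_subject": per_subject,
            "mean_accuracy": float(np.mean([s["accuracy"] for s in per_subject])),
            "mean_null": float(np.mean([s["null_mean"] for s in per_subject])),
        },
    }
    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, indent=2, default=float))
        all_trials.to_csv(out / "trials.csv", index=False)
        all_feats.to_csv(out / "features.csv", index=False)
    return report


def load_real_session(
    signal_path: str | Path, trial_table_path: str | Path
) -> tuple[EpochedRecording, pd.DataFrame]:
    """Load an epoch-aligned recording (FIF or EDF) plus its trial table.

    Returns structures identical to those the synthetic generator produces,
    after schema validation (montage channels, annotation ordering).
    """
    from . import io as session_io

    signal_path = Path(signal_path)
    if signal_path.suffix.lower() == ".edf":
        recording = session_io.read_epochs_edf(signal_path)
    else:
        recording = session_io.read_epochs_fif(signal_path)
    trials = session_io.read_trial_table(trial_table_path)
    return recording, trials
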