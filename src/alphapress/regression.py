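"""Trial-wise linear models, behavioral statistics, and onset detection.

Three model families:

* ``fit_trialwise`` — OLS of a per-trial neural quantity on behavioral
  predictors plus one intercept per subject (the fixed-intercepts model used
  for the significance time courses). With confidence alone this is the
  one-factor model; adding DV, RT, EMG and gaze gives the partial-effect
  model that asks whether confidence explains alpha power beyond them.
* ``fit_confidence_model`` — the reverse regression: confidence on neural
  power and the covariates, with per-subject random intercepts and slopes,
  every variable normalized to its 2.5th-97.5th percentile range so the
  fixed-effect weights are comparable.
* ``divergence_onset`` — first time sample at which two trial groups differ
  (rank-sum p < 0.01) for at least 10 consecutive samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from statsmodels.stats.proportion import proportions_ztest

__all__ = [
    "TrialwiseFit",
    "EffectTrace",
    "percentile_normalize",
    "fit_trialwise",
    "effect_timecourse",
    "fit_confidence_model",
    "divergence_onset",
    "behavioral_stats",
    "channel_significance_map",
]


@dataclass(frozen=True)
class TrialwiseFit:
    """Per-predictor weight, t-statistic and two-sided p-value from one OLS fit."""

    weights: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    n_obs: int


@dataclass(frozen=True)
class EffectTrace:
    """Per-window regression statistics for each predictor.

    ``tstats`` and ``pvalues`` are DataFrames indexed by window center (s),
    one column per predictor.
    """

    times: np.ndarray
    tstats: pd.DataFrame
    pvalues: pd.DataFrame

    def significance_runs(
        self, predictor: str, alpha: float = 0.01, min_run: int = 10
    ) -> list[tuple[float, float]]:
        """Intervals (start, end window center) of ≥ min_run consecutive p < alpha."""
        sig = (self.pvalues[predictor].to_numpy() < alpha).astype(int)
        runs = []
        start = None
        for i, s in enumerate(np.append(sig, 0)):
            if s and start is None:
                start = i
            elif not s and start is not None:
                if i - start >= min_run:
                    runs.append((float(self.times[start]), float(self.times[i - 1])))
                start = None
        return runs


def percentile_normalize(x: np.ndarray, lo: float = 2.5, hi: float = 97.5) -> np.ndarray:
    """Affine rescale mapping the lo-th percentile to 0 and the hi-th to 1."""
    x = np.asarray(x, dtype=float)
    p_lo, p_hi = np.percentile(x, [lo, hi])
    if p_hi <= p_lo:
        raise ValueError("degenerate percentile range")
    return (x - p_lo) / (p_hi - p_lo)


def _design_with_subject_intercepts(
    predictors: pd.DataFrame, subject_ids: np.ndarray
) -> pd.DataFrame:
    dummies = pd.get_dummies(pd.Series(subject_ids, name="subject"), prefix="subject", dtype=float)
    X = pd.concat([predictors.reset_index(drop=True), dummies.reset_index(drop=True)], axis=1)
    return X


def fit_trialwise(
    response: np.ndarray,
    predictors: pd.DataFrame,
    subject_ids: np.ndarray | None = None,
) -> TrialwiseFit:
    """OLS of ``response`` on the predictors with per-subject fixed intercepts.

    Raises ``ValueError`` naming the offending columns when the design
    matrix is rank deficient.
    """
    response = np.asarray(response, dtype=float)
    if subject_ids is None:
        subject_ids = np.zeros(len(response), dtype=int)
    if len(predictors) != len(response):
        raise ValueError("response and predictors must have equal length")
    X = _design_with_subject_intercepts(predictors, np.asarray(subject_ids))
    if len(response) <= X.shape[1]:
        raise ValueError("need more observations than parameters")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # name the columns that do not add rank, scanning left to right
        bad = []
        cols: list[str] = []
        for c in X.columns:
            trial = X[cols + [c]].to_numpy()
            if np.linalg.matrix_rank(trial) == len(cols):
                bad.append(c)
            else:
                cols.append(c)
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")
    fit = sm.OLS(response, X.to_numpy()).fit()
    names = list(X.columns)
    keep = list(predictors.columns)
    idx = [names.index(k) for k in keep]
    return TrialwiseFit(
        weights=pd.Series(fit.params[idx], index=keep),
        tvalues=pd.Series(fit.tvalues[idx], index=keep),
        pvalues=pd.Series(fit.pvalues[idx], index=keep),
        n_obs=len(response),
    )


def effect_timecourse(
    power: np.ndarray,
    window_centers: np.ndarray,
    static_predictors: pd.DataFrame,
    dynamic_predictors: dict[str, np.ndarray] | None = None,
    subject_ids: np.ndarray | None = None,
) -> EffectTrace:
    """Repeat the trial-wise fit at every time window.

    ``power`` is (n_trials, n_windows); ``static_predictors`` holds one value
    per trial (confidence, RT); each entry of ``dynamic_predictors`` is an
    (n_trials, n_windows) array sampled at the window centers (instantaneous
    DV, EMG power, gaze position).
    """
    power = np.asarray(power, dtype=float)
    dynamic_predictors = dynamic_predictors or {}
    names = list(static_predictors.columns) + list(dynamic_predictors)
    t_rows, p_rows = [], []
    for w in range(power.shape[1]):
        cols = {name: static_predictors[name].to_numpy() for name in static_predictors.columns}
        for name, arr in dynamic_predictors.items():
            cols[name] = np.asarray(arr)[:, w]
        fit = fit_trialwise(power[:, w], pd.DataFrame(cols), subject_ids)
        t_rows.append(fit.tvalues)
        p_rows.append(fit.pvalues)
    times = np.asarray(window_centers, dtype=float)
    return EffectTrace(
        times=times,
        tstats=pd.DataFrame(t_rows, index=times)[names],
        pvalues=pd.DataFrame(p_rows, index=times)[names],
    )


def fit_confidence_model(
    data: pd.DataFrame,
    predictors: tuple[str, ...] = ("neural", "dv", "rt", "hand_emg", "eye_pos"),
    response: str = "confidence",
    subject_col: str = "subject",
) -> dict:
    """Mixed model of confidence on neural power and behavioral covariates.

    Every predictor (and the response if continuous) is normalized to its
    2.5th-97.5th percentile range; the model carries a random intercept and
    random slopes per subject (6 terms per subject). Falls back to OLS with
    subject intercepts, with a warning, when the mixed fit fails to
    converge — small synthetic datasets often cannot support 6 variance
    components.

    Returns a dict with ``weights``, ``pvalues`` (pandas Series over the
    predictors) and ``method`` ("mixed" or "ols_fallback").
    """
    if data[subject_col].nunique() < 2:
        raise ValueError("at least 2 subjects are required for the confidence model")
    norm = pd.DataFrame({p: percentile_normalize(data[p].to_numpy()) for p in predictors})
    y = data[response].to_numpy(dtype=float)
    groups = data[subject_col].to_numpy()
    exog = sm.add_constant(norm.to_numpy())
    names = ["const", *predictors]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.MixedLM(y, exog, groups=groups, exog_re=exog)
            fit = model.fit(reml=False, maxiter=200)
        if not fit.converged:
            raise RuntimeError("mixed model did not converge")
        params = pd.Series(fit.fe_params, index=names)
        pvals = pd.Series(np.asarray(fit.pvalues)[: len(names)], index=names)
        method = "mixed"
    except Exception:
        warnings.warn(
            "mixed confidence model failed to converge; falling back to OLS "
            "with per-subject intercepts",
            stacklevel=2,
        )
        flat = fit_trialwise(y, norm, groups)
        params = pd.concat([pd.Series({"const": np.nan}), flat.weights])
        pvals = pd.concat([pd.Series({"const": np.nan}), flat.pvalues])
        method = "ols_fallback"
    return {
        "weights": params[list(predictors)],
        "pvalues": pvals[list(predictors)],
        "method": method,
    }


def divergence_onset(
    group_a: np.ndarray,
    group_b: np.ndarray,
    times: np.ndarray | None = None,
    alpha: float = 0.01,
    min_run: int = 10,
) -> float | None:
    """First time at which the groups separate persistently.

    Runs a Wilcoxon rank-sum test per time sample on the (n_trials, n_times)
    group matrices; the onset is the first sample opening a run of at least
    ``min_run`` consecutive samples with p < alpha, reported as that
    sample's time (or index when ``times`` is None). Returns None when no
    such run exists.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.ndim != 2 or b.ndim != 2 or a.shape[1] != b.shape[1]:
        raise ValueError("groups must be (n_trials, n_times) with matching n_times")
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("each group needs at least 2 trials")
    pvals = scipy.stats.ranksums(a, b, axis=0).pvalue
    sig = pvals < alpha
    count = 0
    for i, s in enumerate(sig):
        count = count + 1 if s else 0
        if count >= min_run:
            start = i - min_run + 1
            return float(times[start]) if times is not None else float(start)
    return None


def behavioral_stats(trials: pd.DataFrame) -> dict:
    """Psychometric, chronometric, confidence and proportion statistics.

    ``trials`` needs columns dv_end, choice ("button"/"saccade"), correct,
    confidence ("sure"/"unsure"), rt_ms; only rows the caller considers
    valid should be passed. Returns a nested dict of fitted parameters and
    p-values.
    """
    if len(trials) < 4:
        raise ValueError("too few trials for behavioral statistics")
    button = (trials["choice"] == "button").to_numpy(dtype=float)
    dv = trials["dv_end"].to_numpy(dtype=float)
    rt = trials["rt_ms"].to_numpy(dtype=float)
    sure = (trials["confidence"] == "sure").to_numpy(dtype=bool)
    correct = trials["correct"].to_numpy(dtype=bool)
    if sure.all() or (~sure).all():
        raise ValueError("need both confidence classes")

    logit_fit = sm.Logit(button, sm.add_constant(dv)).fit(disp=0)
    line_fit = sm.OLS(rt, sm.add_constant(np.abs(dv))).fit()

    acc_sure = float(correct[sure].mean())
    acc_unsure = float(correct[~sure].mean())
    acc_p = float(
        scipy.stats.ranksums(correct[sure].astype(float), correct[~sure].astype(float)).pvalue
    )
    rt_p = float(scipy.stats.ranksums(rt[sure], rt[~sure]).pvalue)

    n = len(trials)
    _, button_p = proportions_ztest(button.sum(), n, value=0.5)

    prev_sure = np.roll(sure, 1)[1:]
    cur_sure = sure[1:]
    seq = {}
    base_rate = float(sure.mean())
    for label, mask in (("after_sure", prev_sure), ("after_unsure", ~prev_sure)):
        k, m = int(cur_sure[mask].sum()), int(mask.sum())
        _, p = proportions_ztest(
            np.array([k, int(sure.sum())]), np.array([m, n])
        )
        seq[label] = {"p_sure": k / m if m else np.nan, "n": m, "p_vs_overall": float(p)}

    return {
        "psychometric": {
            "slope": float(logit_fit.params[1]),
            "intercept": float(logit_fit.params[0]),
            "slope_p": float(logit_fit.pvalues[1]),
        },
        "chronometric": {
            "slope_ms_per_dv": float(line_fit.params[1]),
            "intercept_ms": float(line_fit.params[0]),
            "slope_p": float(line_fit.pvalues[1]),
        },
        "confidence": {
            "p_sure": base_rate,
            "accuracy_sure": acc_sure,
            "accuracy_unsure": acc_unsure,
            "accuracy_p": acc_p,
            "rt_sure_ms": float(rt[sure].mean()),
            "rt_unsure_ms": float(rt[~sure].mean()),
            "rt_p": rt_p,
        },
        "proportions": {
            "p_button": float(button.mean()),
            "button_vs_half_p": float(button_p),
            "sequential": seq,
        },
    }


def channel_significance_map(
    channel_power: np.ndarray,
    channel_names: list[str],
    confidence: np.ndarray,
    subject_ids: np.ndarray | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Confidence weight per channel with a Bonferroni mask.

    ``channel_power`` is (n_trials, n_channels) window-averaged alpha power.
    Each channel gets the one-factor fixed-intercepts regression of power on
    confidence; the mask flags p < alpha / n_channels.
    """
    channel_power = np.asarray(channel_power, dtype=float)
    n_channels = channel_power.shape[1]
    if n_channels != len(channel_names):
        raise ValueError("channel_power and channel_names disagree")
    conf = pd.DataFrame({"confidence": np.asarray(confidence, dtype=float)})
    rows = []
    for c in range(n_channels):
        fit = fit_trialwise(channel_power[:, c], conf, subject_ids)
        rows.append(
            {
                "channel": channel_names[c],
                "weight": fit.weights["confidence"],
                "t": fit.tvalues["confidence"],
                "p": fit.pvalues["confidence"],
            }
        )
    out = pd.DataFrame(rows)
    out["significant"] = out["p"] < alpha / n_channels
    return out
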