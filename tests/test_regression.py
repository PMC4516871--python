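"""Trial-wise models, onset detection, and behavioral statistics."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from alphapress.regression import (
    behavioral_stats,
    channel_significance_map,
    divergence_onset,
    effect_timecourse,
    fit_confidence_model,
    fit_trialwise,
    percentile_normalize,
)


def _subjects(n, k=4):
    return np.repeat([f"S{i}" for i in range(k)], n // k)


class TestTrialwiseOLS:
    def test_exact_noiseless_recovery(self):
        rng = np.random.default_rng(0)
        n = 80
        subj = _subjects(n)
        conf = rng.integers(0, 2, n).astype(float)
        offsets = {s: o for s, o in zip(np.unique(subj), [1.0, -2.0, 0.5, 3.0])}
        y = 2.0 * conf + np.array([offsets[s] for s in subj])
        fit = fit_trialwise(y, pd.DataFrame({"confidence": conf}), subj)
        assert fit.weights["confidence"] == pytest.approx(2.0, abs=1e-10)

    def test_coverage_of_generating_weights(self):
        """95% CIs cover the true weight in at least 93/100 noisy replicates."""
        rng = np.random.default_rng(1)
        n, true_w = 60, 1.5
        covered = 0
        for _ in range(100):
            x = rng.normal(size=n)
            y = true_w * x + rng.normal(size=n)
            fit = fit_trialwise(y, pd.DataFrame({"x": x}))
            se = fit.weights["x"] / fit.tvalues["x"]
            lo, hi = fit.weights["x"] - 2.0 * se, fit.weights["x"] + 2.0 * se
            covered += lo <= true_w <= hi
        assert covered >= 93

    def test_null_pvalues_uniform(self):
        """p-values under no relation are uniform (KS at α=0.01)."""
        rng = np.random.default_rng(2)
        pvals = []
        for _ in range(1000):
            x = rng.normal(size=40)
            y = rng.normal(size=40)
            pvals.append(fit_trialwise(y, pd.DataFrame({"x": x})).pvalues["x"])
        assert scipy.stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_rank_deficiency_names_columns(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=50)
        preds = pd.DataFrame({"a": x, "b": 2 * x})
        with pytest.raises(ValueError, match="b"):
            fit_trialwise(rng.normal(size=50), preds)

    def test_single_factor_agrees_with_padded_model(self):
        """Adding irrelevant-noise covariates barely moves the confidence weight."""
        rng = np.random.default_rng(4)
        n = 400
        conf = rng.integers(0, 2, n).astype(float)
        y = 1.2 * conf + rng.normal(size=n)
        w1 = fit_trialwise(y, pd.DataFrame({"confidence": conf})).weights["confidence"]
        extra = pd.DataFrame(
            {"confidence": conf, "z1": rng.normal(size=n), "z2": rng.normal(size=n)}
        )
        w2 = fit_trialwise(y, extra).weights["confidence"]
        assert w1 == pytest.approx(w2, abs=0.1)


class TestEffectTimecourse:
    def _power(self, rng, n_trials, n_windows, conf, onset_idx, effect):
        p = rng.normal(size=(n_trials, n_windows))
        p[:, onset_idx:] += effect * conf[:, None]
        return p

    def test_injected_onset_recovered(self):
        rng = np.random.default_rng(5)
        n, n_win = 300, 60
        centers = 0.05 + np.arange(n_win) * 0.03  # 30 ms grid
        conf = rng.integers(0, 2, n).astype(float)
        onset_idx = np.argmin(np.abs(centers - 0.5))
        power = self._power(rng, n, n_win, conf, onset_idx, effect=1.5)
        trace = effect_timecourse(power, centers, pd.DataFrame({"confidence": conf}))
        runs = trace.significance_runs("confidence", alpha=0.01, min_run=10)
        assert runs, "no significance run found"
        assert abs(runs[0][0] - 0.5) <= 0.06

    def test_null_rate_calibrated(self):
        rng = np.random.default_rng(6)
        n, n_win = 200, 80
        centers = np.arange(n_win) * 0.03
        conf = rng.integers(0, 2, n).astype(float)
        power = rng.normal(size=(n, n_win))
        trace = effect_timecourse(power, centers, pd.DataFrame({"confidence": conf}))
        frac = (trace.pvalues["confidence"] < 0.01).mean()
        assert frac < 0.05

    def test_shuffling_labels_destroys_run(self):
        rng = np.random.default_rng(7)
        n, n_win = 300, 60
        centers = np.arange(n_win) * 0.03
        conf = rng.integers(0, 2, n).astype(float)
        power = self._power(rng, n, n_win, conf, 20, effect=1.5)
        shuffled = rng.permutation(conf)
        trace = effect_timecourse(power, centers, pd.DataFrame({"confidence": shuffled}))
        assert not trace.significance_runs("confidence", alpha=0.01, min_run=10)


class TestConfidenceModel:
    def test_percentile_normalization_endpoints(self, rng):
        x = rng.normal(size=4000)
        z = percentile_normalize(x)
        assert np.percentile(z, 2.5) == pytest.approx(0.0, abs=1e-9)
        assert np.percentile(z, 97.5) == pytest.approx(1.0, abs=1e-9)

    def _synthetic(self, rng, n_per=150, k=4):
        n = n_per * k
        subj = _subjects(n, k)
        dv = np.abs(rng.normal(1.0, 0.8, n))
        rt = 650 - 40 * dv + rng.normal(0, 40, n)
        alpha = 5.0 - 0.8 * dv + rng.normal(0, 1.0, n)  # power drops with evidence
        emg = rng.normal(size=n)
        eye = rng.normal(size=n)
        # confidence driven by DV (+), RT (−), alpha power (−)
        z = 1.2 * dv - 0.01 * (rt - rt.mean()) - 0.5 * alpha
        conf = (z + rng.normal(0, 1.0, n) > np.median(z)).astype(float)
        return pd.DataFrame(
            {"confidence": conf, "neural": alpha, "dv": dv, "rt": rt,
             "hand_emg": emg, "eye_pos": eye, "subject": subj}
        )

    def test_recovers_generating_signs(self):
        rng = np.random.default_rng(8)
        data = self._synthetic(rng)
        res = fit_confidence_model(data)
        w = res["weights"]
        assert w["dv"] > 0
        assert w["rt"] < 0
        assert w["neural"] < 0

    def test_absent_predictor_is_null(self):
        rng = np.random.default_rng(9)
        hits = 0
        for _ in range(10):
            data = self._synthetic(rng)
            res = fit_confidence_model(data)
            hits += res["pvalues"]["eye_pos"] < 0.05
        assert hits <= 3

    def test_requires_two_subjects(self):
        rng = np.random.default_rng(10)
        data = self._synthetic(rng, n_per=40, k=1)
        with pytest.raises(ValueError):
            fit_confidence_model(data)


class TestDivergenceOnset:
    def test_identical_distributions_give_none(self, rng):
        a = rng.normal(size=(40, 120))
        b = rng.normal(size=(40, 120))
        assert divergence_onset(a, b) is None

    def test_nine_sample_run_insufficient(self, rng):
        a = rng.normal(size=(60, 60))
        b = rng.normal(size=(60, 60))
        b[:, 30:39] += 3.0  # exactly 9 separated samples
        onset = divergence_onset(a, b)
        assert onset is None or onset < 25  # never reported from the short run

    def test_step_change_recovered(self, rng):
        k = 70
        a = rng.normal(size=(80, 150))
        b = rng.normal(size=(80, 150))
        b[:, k:] += 2.0
        onset = divergence_onset(a, b)
        assert onset is not None
        assert abs(onset - k) <= 3

    def test_times_argument_maps_onset(self, rng):
        k = 40
        a = rng.normal(size=(60, 100))
        b = rng.normal(size=(60, 100))
        b[:, k:] += 3.0
        times = np.arange(100) * 0.01
        assert divergence_onset(a, b, times=times) == pytest.approx(0.4, abs=0.03)

    def test_degenerate_groups_error(self, rng):
        with pytest.raises(ValueError):
            divergence_onset(rng.normal(size=(1, 10)), rng.normal(size=(5, 10)))


class TestBehavioralStats:
    def test_recovers_generating_structure(self, long_behavior_session):
        frame = long_behavior_session.trial_frame()
        stats = behavioral_stats(frame[frame["valid"]].reset_index(drop=True))
        subj = long_behavior_session.subject
        assert stats["psychometric"]["slope"] > 0
        assert stats["psychometric"]["slope_p"] < 1e-6
        assert stats["chronometric"]["slope_ms_per_dv"] < 0
        assert stats["chronometric"]["slope_p"] < 0.05
        assert stats["confidence"]["accuracy_sure"] > stats["confidence"]["accuracy_unsure"]
        assert stats["confidence"]["rt_sure_ms"] < stats["confidence"]["rt_unsure_ms"]
        seq = stats["proportions"]["sequential"]
        assert seq["after_sure"]["p_sure"] > seq["after_unsure"]["p_sure"]

    def test_button_fraction_near_half(self, long_behavior_session):
        frame = long_behavior_session.trial_frame()
        stats = behavioral_stats(frame[frame["valid"]].reset_index(drop=True))
        assert abs(stats["proportions"]["p_button"] - 0.5) < 0.05

    def test_decoupled_confidence_is_null(self, rng):
        """Random confidence labels give no accuracy split."""
        n = 600
        dv = rng.normal(size=n)
        frame = pd.DataFrame(
            {
                "dv_end": dv,
                "choice": np.where(rng.uniform(size=n) < scipy.stats.norm.cdf(2 * dv), "button", "saccade"),
                "rt_ms": rng.normal(600, 50, n),
                "confidence": np.where(rng.uniform(size=n) < 0.6, "sure", "unsure"),
            }
        )
        frame["correct"] = (frame["choice"] == "button") == (dv > 0)
        stats = behavioral_stats(frame)
        assert stats["confidence"]["accuracy_p"] > 0.01


class TestChannelMap:
    def test_effect_only_at_injected_channels(self, rng):
        n, chans = 400, [f"C{i}" for i in range(16)]
        conf = rng.integers(0, 2, n).astype(float)
        power = rng.normal(size=(n, 16))
        power[:, 3] += 2.0 * conf
        power[:, 7] += 2.0 * conf
        out = channel_significance_map(power, chans, conf)
        assert set(out[out["significant"]]["channel"]) == {"C3", "C7"}

    def test_no_effect_bonferroni_bound(self, rng):
        false_positives = 0
        for _ in range(20):
            conf = rng.integers(0, 2, 200).astype(float)
            power = rng.normal(size=(200, 16))
            out = channel_significance_map(power, [f"C{i}" for i in range(16)], conf)
            false_positives += out["significant"].sum()
        assert false_positives / 20 < 1.0


class TestPartialEffect:
    """Does confidence explain alpha power beyond the DV? The regression must
    say yes exactly when the generator drives alpha with confidence beyond DV."""

    def _fit_conf_p(self, rng, conf_drive):
        n = 500
        dv = np.abs(rng.normal(1.0, 0.8, n))
        conf = (dv + rng.normal(0, 0.7, n) > 1.0).astype(float)
        alpha = -0.8 * dv + conf_drive * conf + rng.normal(0, 0.6, n)
        preds = pd.DataFrame({"confidence": conf, "dv": dv})
        return fit_trialwise(alpha, preds).pvalues["confidence"]

    def test_confidence_term_significant_iff_generated(self):
        rng = np.random.default_rng(11)
        assert self._fit_conf_p(rng, conf_drive=-0.6) < 0.01
        null_ps = [self._fit_conf_p(rng, conf_drive=0.0) for _ in range(10)]
        assert np.mean(np.array(null_ps) < 0.05) <= 0.3
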