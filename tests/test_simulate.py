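"""Behavioral generator and epoch synthesis."""

import dataclasses

import numpy as np
import pytest
import scipy.stats

from alphapress.signals import bandpass_alpha, sliding_power
from alphapress.simulate import (
    ALL_CHANNELS,
    EEG_CHANNELS,
    SimulatedSubject,
    TrialRecord,
    compute_feedback_points,
    run_session,
    simulate_choice,
    simulate_confidence,
    simulate_rt,
    synthesize_epoch,
)
from alphapress.stimulus import generate_click_train


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


def _trial(**kw):
    rng = np.random.default_rng(0)
    defaults = dict(
        index=0, stimulus=generate_click_train(32, 20, rng), dv_end=1.5,
        choice="button", correct=True, confidence="sure", rt_ms=500.0,
        valid=True, invalid_reason="none", feedback_points=20, beta=8.0,
    )
    defaults.update(kw)
    return TrialRecord(**defaults)


class TestChoice:
    def test_symmetry_at_zero(self, rng):
        subj = SimulatedSubject(lapse_rate=0.0)
        draws = [simulate_choice(0.0, subj, rng) == "button" for _ in range(8000)]
        assert np.mean(draws) == pytest.approx(0.5, abs=0.02)

    def test_monte_carlo_matches_logistic(self):
        subj = SimulatedSubject(choice_slope=1.5, lapse_rate=0.0)
        rng = np.random.default_rng(3)
        n = 20_000
        frac = np.mean([simulate_choice(1.0, subj, rng) == "button" for _ in range(n)])
        p = _expit(1.5)
        se = np.sqrt(p * (1 - p) / n)
        assert abs(frac - p) < 3 * se

    def test_strong_evidence_hits_lapse_ceiling(self, rng):
        subj = SimulatedSubject(choice_slope=1.5, lapse_rate=0.1)
        frac = np.mean([simulate_choice(50.0, subj, rng) == "button" for _ in range(4000)])
        assert frac == pytest.approx(1 - 0.1 / 2, abs=0.02)


class TestRT:
    def test_linear_arithmetic(self):
        subj = SimulatedSubject(rt_intercept_ms=600, rt_slope_ms_per_dv=-30, rt_noise_ms=0.0)
        rt, reason = simulate_rt(2.0, subj, np.random.default_rng(0))
        assert rt == pytest.approx(540.0)
        assert reason == "none"

    def test_out_of_window_marks_invalid(self):
        late = SimulatedSubject(rt_intercept_ms=900, rt_noise_ms=0.0)
        assert simulate_rt(0.0, late, np.random.default_rng(0))[1] == "too_late"
        early = SimulatedSubject(rt_intercept_ms=100, rt_noise_ms=0.0)
        assert simulate_rt(0.0, early, np.random.default_rng(0))[1] == "too_early"

    def test_sure_trials_are_faster(self, long_behavior_session):
        v = long_behavior_session.valid_trials
        rt_sure = np.mean([t.rt_ms for t in v if t.confidence == "sure"])
        rt_unsure = np.mean([t.rt_ms for t in v if t.confidence == "unsure"])
        assert rt_sure < rt_unsure


class TestConfidence:
    def test_deterministic_threshold_in_noise_free_limit(self, rng):
        subj = SimulatedSubject(confidence_noise=1e-12, sequential_confidence_shift=0.0)
        th = subj.confidence_threshold
        assert simulate_confidence(th + 0.01, None, subj, rng) == "sure"
        assert simulate_confidence(th - 0.01, None, subj, rng) == "unsure"

    def test_p_sure_nondecreasing_in_dv(self):
        subj = SimulatedSubject()
        fracs = []
        for dv in [0.0, 0.5, 1.0, 2.0, 4.0]:
            rng = np.random.default_rng(11)
            fracs.append(
                np.mean([simulate_confidence(dv, None, subj, rng) == "sure" for _ in range(3000)])
            )
        assert np.all(np.diff(fracs) >= -0.02)

    def test_sure_more_accurate_than_unsure(self, long_behavior_session):
        v = long_behavior_session.valid_trials
        acc_sure = np.mean([t.correct for t in v if t.confidence == "sure"])
        acc_unsure = np.mean([t.correct for t in v if t.confidence == "unsure"])
        assert acc_sure > acc_unsure

    def test_sequential_shift_direction(self):
        subj = SimulatedSubject()
        rng = np.random.default_rng(5)
        dvs = np.abs(rng.normal(1.0, 0.8, 8000))
        after_sure = np.mean([simulate_confidence(d, "sure", subj, rng) == "sure" for d in dvs])
        after_unsure = np.mean([simulate_confidence(d, "unsure", subj, rng) == "sure" for d in dvs])
        assert after_sure > after_unsure


class TestFeedback:
    @pytest.mark.parametrize(
        "correct,e,conf,expected",
        [
            (True, 0.8, "sure", 20),
            (False, 0.2, "sure", -20),
            (True, 0.2, "unsure", 20),
            (True, 0.2, "sure", 0),
            (False, 0.8, "unsure", -20),
            (True, 0.5, "sure", 20),  # boundary counts as easy
        ],
    )
    def test_rules(self, correct, e, conf, expected):
        assert compute_feedback_points(correct, e, conf) == expected


class TestEpochSynthesis:
    def test_determinism(self):
        subj = SimulatedSubject()
        tr = _trial()
        a = synthesize_epoch(tr, subj, np.random.default_rng(77))
        b = synthesize_epoch(tr, subj, np.random.default_rng(77))
        assert np.array_equal(a, b)
        assert a.shape == (len(ALL_CHANNELS), 768)

    def test_refuses_invalid_trial(self):
        tr = _trial(valid=False, invalid_reason="too_late", rt_ms=900.0)
        with pytest.raises(ValueError):
            synthesize_epoch(tr, SimulatedSubject(), np.random.default_rng(0))

    def test_zero_effect_is_null(self):
        """With alpha_effect=0, sure and unsure alpha power are indistinguishable."""
        subj = SimulatedSubject(alpha_effect=0.0)
        rng = np.random.default_rng(2)
        p3 = ALL_CHANNELS.index("P3")
        powers = {"sure": [], "unsure": []}
        for conf in powers:
            for _ in range(100):
                tr = _trial(confidence=conf)
                epoch = synthesize_epoch(tr, subj, rng)
                filt = bandpass_alpha(epoch[p3])
                ps = sliding_power(filt, tmin=-0.5)
                mask = (ps.window_centers > 0.4) & (ps.window_centers < 1.0)
                powers[conf].append(ps.values[mask].mean())
        p = scipy.stats.ranksums(powers["sure"], powers["unsure"]).pvalue
        assert p > 0.01

    def test_effect_lowers_sure_alpha_power(self):
        subj = SimulatedSubject(alpha_effect=0.6)
        rng = np.random.default_rng(2)
        p3 = ALL_CHANNELS.index("P3")
        means = {}
        for conf in ("sure", "unsure"):
            vals = []
            for _ in range(60):
                tr = _trial(confidence=conf, dv_end=1.0)
                epoch = synthesize_epoch(tr, subj, rng)
                filt = bandpass_alpha(epoch[p3])
                ps = sliding_power(filt, tmin=-0.5)
                mask = (ps.window_centers > 0.4) & (ps.window_centers < 1.0)
                vals.append(ps.values[mask].mean())
            means[conf] = np.mean(vals)
        assert means["sure"] < means["unsure"]

    def test_emg_burst_only_on_button_trials(self):
        subj = SimulatedSubject()
        rng = np.random.default_rng(4)
        emg_i = ALL_CHANNELS.index("EMG_FCR")
        t = -0.5 + np.arange(768) / 256.0
        btn = synthesize_epoch(_trial(choice="button", rt_ms=500.0), subj, rng)
        sac = synthesize_epoch(_trial(choice="saccade", correct=False, rt_ms=500.0), subj, rng)
        move = 1.5  # stimulus 1 s + 500 ms RT
        pre = (t > 0.0) & (t < move - 0.3)
        burst = (t > move - 0.05) & (t < move + 0.15)
        assert btn[emg_i][burst].std() > 4 * btn[emg_i][pre].std()
        assert sac[emg_i][burst].std() < 2 * sac[emg_i][pre].std()

    def test_gaze_ramps_left_on_saccade_trials(self):
        subj = SimulatedSubject()
        rng = np.random.default_rng(4)
        gx = ALL_CHANNELS.index("GAZE_X")
        sac = synthesize_epoch(_trial(choice="saccade", correct=False, rt_ms=400.0), subj, rng)
        btn = synthesize_epoch(_trial(choice="button", rt_ms=400.0), subj, rng)
        assert sac[gx][-50:].mean() < -10.0
        assert abs(btn[gx][-50:].mean()) < 2.0


class TestSession:
    def test_deterministic_trial_table(self):
        a = run_session(40, seed=5, synthesize_signals=False).trial_frame()
        b = run_session(40, seed=5, synthesize_signals=False).trial_frame()
        assert a.equals(b)

    def test_trial_invariants(self, session_with_signals):
        for tr in session_with_signals.trials:
            s = tr.stimulus
            assert s.c_l + s.c_r == s.omega
            if tr.valid:
                assert 200 < tr.rt_ms <= 800
                assert tr.invalid_reason == "none"
                expected = (tr.choice == "button" and s.c_r > s.c_l) or (
                    tr.choice == "saccade" and s.c_l > s.c_r
                )
                assert tr.correct == expected
            else:
                assert tr.invalid_reason in (
                    "too_early", "too_late", "both", "wrong_saccade", "fixation_break",
                )

    def test_epochs_only_for_valid_trials(self, session_with_signals):
        ep = session_with_signals.epochs
        valid_idx = {t.index for t in session_with_signals.valid_trials}
        assert set(ep.events["trial_index"]) == valid_idx
        assert ep.data.shape[1] == len(ALL_CHANNELS)

    def test_choice_fraction_near_half(self, long_behavior_session):
        v = long_behavior_session.valid_trials
        frac = np.mean([t.choice == "button" for t in v])
        n = len(v)
        assert abs(frac - 0.5) < 4 * np.sqrt(0.25 / n) + 0.02

    def test_insensitive_observer_saturates_beta(self, caplog):
        """Accuracy that ignores difficulty drives β to its bound, with a log flag."""
        import logging

        from alphapress.stimulus import BETA_MAX, AdaptiveState

        state = AdaptiveState()
        with caplog.at_level(logging.WARNING, logger="alphapress.stimulus"):
            for _ in range(600):
                state.record(True)
                state.step()
        assert state.beta == BETA_MAX
        assert any("saturated" in r.message for r in caplog.records)

    def test_alpha_contrast_scales_with_effect(self):
        """Sure-vs-unsure alpha contrast grows monotonically with alpha_effect."""
        contrasts = []
        for eff in (0.0, 0.4, 0.8):
            subj = SimulatedSubject(alpha_effect=eff)
            rng = np.random.default_rng(31)
            p3 = ALL_CHANNELS.index("P3")
            vals = {"sure": [], "unsure": []}
            for conf in vals:
                for _ in range(40):
                    epoch = synthesize_epoch(_trial(confidence=conf, dv_end=1.0), subj, rng)
                    ps = sliding_power(bandpass_alpha(epoch[p3]), tmin=-0.5)
                    mask = (ps.window_centers > 0.4) & (ps.window_centers < 1.0)
                    vals[conf].append(ps.values[mask].mean())
            contrasts.append(np.mean(vals["unsure"]) - np.mean(vals["sure"]))
        assert contrasts[0] < contrasts[1] < contrasts[2]
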