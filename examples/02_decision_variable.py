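"""The click-by-click log-likelihood-ratio decision variable and behavior.

Estimates the click-side likelihoods from a simulated session, rebuilds the
running logLR for one trial, and summarizes the psychometric (choice vs DV)
and chronometric (RT vs |DV|) relations.
"""

import numpy as np

from alphapress import behavioral_stats, compute_dv_trace, run_session
from alphapress.simulate import SimulatedSubject

session = run_session(1500, SimulatedSubject(), seed=2, synthesize_signals=False)

t = session.table
print(f"P(right click | button):  {t.p_right_given_button:.3f}")
print(f"P(right click | saccade): {t.p_right_given_saccade:.3f}")

trial = session.valid_trials[0]
trace = compute_dv_trace(trial.stimulus, t)
print(f"\ntrial 0: {trial.stimulus.c_r} right / {trial.stimulus.c_l} left clicks, "
      f"DV end = {trace.dv_end:+.2f}, choice = {trial.choice}")

frame = session.trial_frame()
stats = behavioral_stats(frame[frame["valid"]].reset_index(drop=True))
print(f"\npsychometric slope:   {stats['psychometric']['slope']:.2f} per DV unit "
      f"(p = {stats['psychometric']['slope_p']:.1e})")
print(f"chronometric slope:   {stats['chronometric']['slope_ms_per_dv']:.1f} ms per |DV| unit "
      f"(p = {stats['chronometric']['slope_p']:.1e})")
c = stats["confidence"]
print(f"accuracy sure/unsure: {100 * c['accuracy_sure']:.1f}% / {100 * c['accuracy_unsure']:.1f}%")
print(f"RT sure/unsure:       {c['rt_sure_ms']:.0f} / {c['rt_unsure_ms']:.0f} ms")
# Positive psychometric slope: the more rightward evidence, the more button
# presses. Negative chronometric slope: stronger evidence, faster responses.
# Sure reports go with higher accuracy and faster RTs.
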