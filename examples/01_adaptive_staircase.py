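"""Closed-loop adaptive difficulty: hold a simulated listener at 75% correct.

Runs one 2000-trial session in which every trial draws a target evidence
level, picks the nearest pre-generated click train at the current
sensitivity beta, and updates beta from accuracy over the last 20 valid
trials.
"""

import numpy as np

from alphapress import run_session
from alphapress.simulate import SimulatedSubject

session = run_session(2000, SimulatedSubject(), seed=1, synthesize_signals=False)

post = [t.correct for t in session.trials[500:] if t.valid]
beta = session.beta_history
print(f"valid trials:            {len(session.valid_trials)} / {len(session.trials)}")
print(f"accuracy after burn-in:  {100 * np.mean(post):.1f}%  (set point 75%)")
print(f"beta start -> median:    {beta[0]:.1f} -> {np.median(beta[500:]):.1f}")
print(f"beta 5th-95th percentile: {np.percentile(beta[500:], 5):.1f} - "
      f"{np.percentile(beta[500:], 95):.1f}")
# Accuracy should sit within a few points of 75%: the multiplicative update
# raises beta (shrinking the click-count imbalance, so harder trials) when
# the trailing window runs above 75% and lowers it below.
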