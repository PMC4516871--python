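"""Trial-wise regression: does confidence explain alpha power beyond the DV?

Fits the one-factor and the partial-effect models on per-trial alpha
features, maps the confidence effect across channels with a Bonferroni
mask, and fits the reverse mixed-effects model of confidence on neural
power and covariates.
"""

import numpy as np
import pandas as pd

from alphapress import fit_confidence_model, fit_trialwise, run_session
from alphapress.pipeline import session_features
from alphapress.regression import channel_significance_map
from alphapress.signals import bandpass_alpha, car_rereference, reject_artifact_trials, sliding_power
from alphapress.simulate import EEG_CHANNELS, SimulatedSubject

features = []
for s, seed in enumerate([40, 41, 42]):
    session = run_session(250, SimulatedSubject(subject_id=f"S{s + 1:02d}"), seed=seed)
    features.append(session_features(session))
feats = pd.concat(features, ignore_index=True)
btn = feats[feats["choice"] == "button"].reset_index(drop=True)
print(f"{len(btn)} button trials from 3 subjects")

conf = (btn["confidence"] == "sure").astype(float)
one = fit_trialwise(btn["neural"], pd.DataFrame({"confidence": conf}), btn["subject"])
full = fit_trialwise(
    btn["neural"],
    pd.DataFrame({"confidence": conf, "dv": btn["dv_end"], "rt": btn["rt_ms"],
                  "emg": btn["hand_emg"], "eye": btn["eye_pos"]}),
    btn["subject"],
)
print(f"confidence alone:      weight {one.weights['confidence']:+.3f}, "
      f"p = {one.pvalues['confidence']:.1e}")
print(f"confidence + controls: weight {full.weights['confidence']:+.3f}, "
      f"p = {full.pvalues['confidence']:.1e}")
# The confidence term surviving DV/RT/EMG/gaze inclusion is the package's
# core partial-effect check.

model = fit_confidence_model(
    btn.assign(confidence=conf, rt=btn["rt_ms"]),
    predictors=("neural", "dv_end", "rt", "hand_emg", "eye_pos"),
)
print(f"\nreverse model ({model['method']}): normalized weights")
for name, w in model["weights"].items():
    print(f"  {name:9s} {w:+.3f}  (p = {model['pvalues'][name]:.3g})")
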