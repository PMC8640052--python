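"""Simulate one trial's gaze trace and recover its events and metrics.

A synthetic observer pursues the approaching car with gain 0.9, making
catch-up and exploratory saccades; the detector and metric extraction then
measure what was generated.
"""

import numpy as np

from crossgaze import ObserverParams, SceneConfig, TrialSpec, simulate_gaze
from crossgaze.metrics import compute_trial_metrics
from crossgaze.scene import make_trajectory

scene = SceneConfig()
trial = TrialSpec("p01", "speed", 0, 0, 50.0, 3.04, True, "right")
traj = make_trajectory(50.0, 3.04, "right", scene, sample_rate=1000.0)

params = ObserverParams(pursuit_gain_mean=0.9, pursuit_gain_sd=0.0)
trace = simulate_gaze(trial, traj, params, seed=3, scene=scene)
print(f"simulated {len(trace)} samples at {trace.sample_rate:.0f} Hz; "
      f"{len(trace.truth.saccades)} ground-truth saccades, "
      f"{len(trace.truth.blinks)} blinks")

m = compute_trial_metrics(trace, traj, scene)
print(f"pursuit gain {m.gain:.2f} (generative 0.90)")
print(f"saccades counted {m.n_saccades} (first after onset removed), "
      f"mean amplitude {m.mean_amplitude:.2f} deg")
print(f"abs deviation from the vehicle-AOI center: "
      f"{m.abs_dev_h:.2f} deg horizontal, {m.abs_dev_v:.2f} deg vertical")
# Gain near the generative value shows that event interpolation and the
# angular-velocity filtering leave the pursuit estimate unbiased.
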