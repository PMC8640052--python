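"""Which cues drive "earlier" judgements? Dominance analysis.

Compares a synthetic participant (who also weighs vehicle distance) with a
noise-matched ideal observer that responds to time-to-arrival alone.  Any
dominance the ideal observer grants the other cues reflects the design
grid's built-in covariation, not strategy.
"""

import numpy as np
import pandas as pd

from crossgaze import DesignGrid, ObserverParams, TheoreticalObserverSpec
from crossgaze.dominance import (
    general_dominance,
    participant_dominance,
    theoretical_observer_responses,
    trial_cue_matrix,
)
from crossgaze.observer import simulate_response
from crossgaze.psychometrics import fit_from_trials
from crossgaze.scene import make_design

grid = DesignGrid()
params = ObserverParams()
rng = np.random.default_rng(1)
rows = []
for rep in range(3):
    for t in make_design(grid, seed=rep, task="tta"):
        r = simulate_response(t, params, seed=int(rng.integers(2**31)), grid=grid)
        rows.append({"task": "tta", "comparison_speed": t.comparison_speed,
                     "comparison_tta": t.comparison_tta,
                     "standard_first": t.standard_first, **r})
trials = pd.DataFrame(rows)

part = participant_dominance(trials, "tta", grid)
fit = fit_from_trials(trials, "tta", grid.standard_tta)
spec = TheoreticalObserverSpec("earlier-if-tta-smaller",
                               noise_sd=fit.slope_sigma / np.sqrt(2), seed=2)
theo_choices = theoretical_observer_responses(trials, spec, grid)
theo = general_dominance(theo_choices, trial_cue_matrix(trials, grid))

print(f"{'cue':8s} {'participant':>12s} {'ideal observer':>15s}")
for cue in ("speed", "tta", "start", "end"):
    print(f"{cue:8s} {part.general_dominance[cue]:12.3f} "
          f"{theo.general_dominance[cue]:15.3f}")
print(f"{'total R2':8s} {part.r2m_full:12.3f} {theo.r2m_full:15.3f}")
# The participant's start/end-distance dominance clearly exceeds the ideal
# observer's, whose distance shares reflect grid covariation alone: the
# signature of over-reliance on vehicle position.
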