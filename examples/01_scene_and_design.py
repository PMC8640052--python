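"""Scene geometry and experimental design.

Builds the default road-crossing scene, prints the kinematics of the
standard stimulus and the size of the trial list.
"""

from crossgaze import DesignGrid, SceneConfig, angular_size, make_design
from crossgaze.scene import KMH_TO_MS, start_distance

scene = SceneConfig()
grid = DesignGrid()

v = grid.standard_speed * KMH_TO_MS
d0 = start_distance(v, grid.standard_tta, scene.display_duration)
print(f"standard vehicle: {grid.standard_speed:.0f} km/h, "
      f"remaining TTA {grid.standard_tta} s")
print(f"  starts {d0:.1f} m from the stopping line, "
      f"disappears at {v * grid.standard_tta:.1f} m")
# The front plane of the car (1.82 m wide) spans about 2 visual degrees at
# 50 m in the world; on the rendered screen it is compressed to under 1 deg.
print(f"  front plane at 50 m: {angular_size(1.82, 50):.2f} deg of visual angle")

trials = make_design(grid, seed=1)
combos = {(t.comparison_speed, t.comparison_tta) for t in trials}
print(f"one session: {len(trials)} trials covering {len(combos)} unique "
      f"speed x TTA comparisons in {grid.n_blocks} blocks")
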