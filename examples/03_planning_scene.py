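"""Drive the headless planning scene and mirror it over the wire.

Creates screws from the fixed catalog (3 diameters x 7 lengths), cycles
their dimensions the way the planner's next-screw/next-diameter/next-length
controls do, poses them, then rebuilds a second scene purely from the queued
TRANSFORM messages - the mirroring that keeps planner and reslicer in sync.
"""

import numpy as np

from igtplan.messages import RigidTransform
from igtplan.scene import PlanningScene, reconstruct_scene

scene = PlanningScene(spine_model_path="spine.stl")
print(f"catalog: diameters {scene.catalog.diameters} mm, "
      f"lengths {scene.catalog.lengths} mm")

for level in ("L4", "L3"):
    for side, x in (("left", -15.0), ("right", 15.0)):
        screw = scene.create_screw(level=level, side=side)
        scene.set_pose(screw.id, RigidTransform.from_z_axis(
            [0.0, 1.0, 0.0], np.array([x, -35.0, 0.0])
        ))

scene.next_diameter()  # active screw: 4.5 -> 5.0 mm
scene.next_length()    # 30 -> 35 mm
active = scene.active_screw
print(f"{len(scene.screws)} screws; active {active.id}: "
      f"diameter {active.diameter} mm, length {active.length} mm")

messages = scene.drain_messages()
print(f"{len(messages)} TRANSFORM messages queued (one per change)")

mirror = reconstruct_scene(messages)
match = all(
    theirs.pose.isclose(ours.pose, atol=1e-4)
    and (theirs.diameter, theirs.length) == (ours.diameter, ours.length)
    for ours, theirs in zip(scene.screws, mirror.screws)
)
print(f"mirror scene rebuilt from the wire: {len(mirror.screws)} screws, "
      f"poses and dimensions match: {match}")
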