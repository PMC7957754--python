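"""Landmark-referenced longitudinal SWV profile of a tendon-like structure.

Builds a structure whose SWV varies along its long axis (softer near the
insertions, stiffer mid-substance), reconstructs it from a simulated sweep,
anchors it to two landmarks and extracts the Gaussian-kernel (sigma = 5 mm)
profile of SWV versus relative longitudinal position.
"""

import numpy as np

from swvm import (
    AcquisitionModel,
    LandmarkPair,
    Phantom,
    longitudinal_profile,
    orient_to_landmarks,
    reconstruct,
)
from swvm.geometry import Frame, Pose, RigidTransform, Sweep

# emulate an axis-varying structure directly with frames whose value depends
# on the sweep position z: v(z) = 1.8 + 0.8 sin(pi z / 60)
rng = np.random.default_rng(0)
frames, poses = [], []
for i, z in enumerate(np.arange(0.0, 60.0, 1.5)):
    v = 1.8 + 0.8 * np.sin(np.pi * z / 60.0)
    px = np.abs(rng.normal(v, 0.1, (12, 12)))
    frames.append(Frame(float(i), px, (1.0, 1.0)))
    poses.append(Pose(float(i), RigidTransform(
        RigidTransform.identity().rotation, np.array([0.0, 0.0, z]))))
sweep = Sweep(frames=frames, poses=poses)

grid = reconstruct(sweep, spacing=0.5)
landmarks = LandmarkPair(distal=(6, 6, 0), proximal=(6, 6, 60))
samples = orient_to_landmarks(grid, None, landmarks)
prof = longitudinal_profile(samples, kernel_sigma_mm=5.0, n_positions=101)

for pos in (0.0, 0.25, 0.5, 0.75, 1.0):
    j = int(pos * 100)
    truth = 1.8 + 0.8 * np.sin(np.pi * pos)
    print(f"position {pos:4.2f}: SWV {prof.values[j]:.3f} +/- {prof.se[j]:.3f} m/s"
          f"   (field value here: {truth:.3f})")
print("-> the profile tracks the along-axis stiffness variation; the 5 mm "
      "kernel smooths over ~1/12 of this 60 mm structure.")
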