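"""Simulate a tracked freehand sweep and reconstruct a 3D SWV volume.

A virtual probe translates at 3 mm/s across a phantom containing a stiff
cylinder (4.04 m/s) in a 1.0 m/s background, acquiring SWV frames at 2 Hz
while an optical tracker reports jittered poses at 7 Hz.  The frames are
binned into a 0.5 mm voxel grid and the inclusion is summarised with the
dispersion-weighted mean.
"""

import numpy as np

from swvm import (
    AcquisitionModel,
    Inclusion,
    Phantom,
    inclusion_mask,
    reconstruct,
    simulate_sweep,
    weighted_mean_swv,
)

phantom = Phantom(
    background_swv=1.0,
    inclusions=(
        Inclusion("cylinder", center=np.array([10.0, 10.0, 0.0]), radius=6.0,
                  swv=4.04, axis=np.array([0.0, 0.0, 1.0]), length=60.0),
    ),
)
acq = AcquisitionModel(sweep_speed=3.0, noise_sd=0.1, dropout_prob=0.1,
                       frame_shape=(20, 20), seed=1)
sweep = simulate_sweep(phantom, acq, start=(0, 0, -15), end=(0, 0, 15))

grid = reconstruct(sweep, spacing=0.5)
mask = inclusion_mask(grid, phantom, 0, margin_mm=1.5)
mean = weighted_mean_swv(grid, mask)

print(f"SWE frames acquired : {len(sweep.frames_of('swe'))}")
print(f"poses recorded      : {len(sweep.poses)}")
print(f"grid dims           : {grid.dims}, {int(grid.nonempty.sum())} non-empty voxels")
print(f"inclusion mean SWV  : {mean:.3f} m/s (truth 4.040)")
print("-> the weighted mean recovers the inclusion stiffness despite 10% "
      "dropout and 0.1 m/s pixel noise.")
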