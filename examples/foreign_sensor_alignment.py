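"""Align an acceleration-only trace from a foreign sensor convention.

Long-term-monitoring recordings often come as three acceleration channels in
m/s² with a device-specific axis order.  An AxisUnitMap (permutation, sign
flips, per-group unit scale) converts them into the package's internal
convention (g, canonical axis order); the map composes with its inverse to
the identity, so conversions are loss-free.
"""

import numpy as np

from fallnet import AxisUnitMap, SensorTrace, convert_axes_units
from fallnet.io import gravity_units_map

# a standing-still trace recorded in m/s2, with the vertical on axis 0
rng = np.random.default_rng(5)
samples = np.zeros((300, 3))
samples[:, 0] = 9.81 + rng.normal(0, 0.2, 300)  # vertical
samples[:, 1:] = rng.normal(0, 0.2, (300, 2))
foreign = SensorTrace("F01-subject", "F01", 1, 100.0, samples)

# move the vertical to axis 2 (internal convention) and rescale m/s2 -> g
align = AxisUnitMap(permutation=(1, 2, 0), signs=(1, 1, 1),
                    unit_scale=(1 / 9.81,))
aligned = convert_axes_units(foreign, align)
print(f"foreign vertical mean: {foreign.samples[:, 0].mean():6.2f} m/s2 on axis 0")
print(f"aligned vertical mean: {aligned.samples[:, 2].mean():6.2f} g    on axis 2")

back = convert_axes_units(aligned, align.inverse())
print("round trip exact:", np.allclose(back.samples, foreign.samples, atol=1e-12))

print("\ndefault unit-only map (orientation must be confirmed per device):")
print(gravity_units_map())
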