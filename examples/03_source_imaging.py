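"""Distributed inverse imaging: forward project a source, localize it.

Builds a brain-like source grid inside a homogeneous-sphere head model,
computes the LAURA-regularized inverse, and recovers the location of a
noiseless test dipole.  Localization uses the resolution-standardized
source power; the raw current density is also shown to illustrate the
depth bias of weighted-minimum-norm estimates.
"""

import numpy as np

from evtopo import (
    build_laura_inverse,
    build_source_space,
    default_montage,
    leadfield_single_sphere,
)
from evtopo.sources import localization_map

montage = default_montage()
space = build_source_space(60.0, 14.0, connectivity=26, zmin_mm=-24.0)
lead = leadfield_single_sphere(space, montage, head_radius_mm=85.0)
inv = build_laura_inverse(lead, alpha=0.0)
print(f"source space: {space.n_nodes} nodes on a {space.spacing:.0f} mm grid")

true_node = int(np.flatnonzero(space.interior_mask())[5])
moment = np.array([0.4, -0.3, 0.87])
scalp = lead.matrix[:, 3 * true_node : 3 * true_node + 3] @ moment

std_power = localization_map(inv, lead, scalp)
raw_density = np.linalg.norm(inv.apply(scalp).reshape(-1, 3), axis=1)

for name, est in (
    ("standardized power", int(np.argmax(std_power))),
    ("raw density       ", int(np.argmax(raw_density))),
):
    err = np.linalg.norm(space.nodes[est] - space.nodes[true_node])
    print(f"{name}: estimated node {est}, error {err:.1f} mm "
          f"({err / space.spacing:.1f} grid steps)")
# The standardized estimate lands on (or next to) the true node; the raw
# density peak drifts toward superficial nodes -- which is why the
# factorial statistics compare raw densities across conditions at fixed
# node, where that bias cancels, while localization uses standardization.
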