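"""Non-crystallographic symmetry averaging as an extra constraint.

When the asymmetric unit carries an internal rotational symmetry (for
example a Cn helical barrel), averaging the density over the n
rotation images every iteration adds a powerful constraint that can
compensate for low solvent content.  Axis order, direction and position
are declared by the user.
"""

import numpy as np

from evophase import NCSAverager, build_rotation_operators, ncs_average
from evophase.config import NCSConfig
from evophase.grid import DensityGrid
from evophase.lattice import GridSpec, UnitCell

spec = GridSpec(dims=(16, 16, 16), cell=UnitCell(16.0, 16.0, 16.0), d_min=4.0)
ncs = NCSConfig(order=4, axis_direction=(0, 0, 1), axis_point=(0, 0, 0))

ops = build_rotation_operators(ncs)
print(f"C{ncs.order} about z: {len(ops)} rotation operators, "
      f"first non-identity maps (1,0,0) -> "
      f"{tuple(np.round(ops[1] @ [1.0, 0.0, 0.0], 3))}")

rng = np.random.default_rng(0)
g = DensityGrid(spec, rng.normal(size=spec.dims))
g_sym = ncs_average(g, ncs)
again = ncs_average(g_sym, ncs)
print(f"averaging an averaged map changes it by "
      f"{np.abs(again.values - g_sym.values).max():.2e} (idempotent)")

noise = rng.normal(scale=0.3, size=spec.dims)
noisy = DensityGrid(spec, g_sym.values + noise)
cleaned = NCSAverager(ncs, spec).average(noisy)
ratio = noise.var() / (cleaned.values - g_sym.values).var()
print(f"noise variance reduced {ratio:.1f}-fold by C4 averaging "
      f"(expected about {ncs.order})")
# Averaging over n rotation images suppresses the asymmetric component
# of the noise by roughly a factor n — the same mechanism that lets
# NCS-bearing crystals phase successfully at low solvent content.
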