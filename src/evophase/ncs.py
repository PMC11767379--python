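"""Real-space averaging over known rotational non-crystallographic symmetry.

For targets whose asymmetric unit carries an internal Cn rotation (for
example an engineered seven-helix barrel), averaging the density over
the n rotation images is a powerful extra constraint, applied every
iteration in addition to the solvent constraint.  The axis direction,
its position and the rotation order are inputs; determining them from
the data (self-rotation Patterson analysis) is outside this package's
scope.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import map_coordinates

from .config import NCSConfig
from .grid import DensityGrid
from .lattice import GridSpec
from .modify import EnvelopeMask, determine_envelope

__all__ = [
    "NCSConfig",
    "build_rotation_operators",
    "ncs_average",
    "NCSAverager",
    "core_mask_from_weighted_density",
]


def _rotation_about_axis(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit axis."""
    axis = np.asarray(axis, dtype=np.float64)
    axis = axis / np.linalg.norm(axis)
    k = np.array([
        [0.0, -axis[2], axis[1]],
        [axis[2], 0.0, -axis[0]],
        [-axis[1], axis[0], 0.0],
    ])
    return np.eye(3) + np.sin(angle) * k + (1.0 - np.cos(angle)) * (k @ k)


def build_rotation_operators(spec: NCSConfig) -> list[np.ndarray]:
    """The n proper rotations by 2 pi k / n about the declared axis.

    Matrices act in the orthogonal (angstrom) frame; k = 0 is the
    identity.  Axis position is handled separately by the averager.
    """
    return [
        _rotation_about_axis(np.asarray(spec.axis_direction, dtype=np.float64),
                             2.0 * np.pi * k / spec.order)
        for k in range(spec.order)
    ]


class NCSAverager:
    """Caches the rotation-image grid coordinates for repeated use.

    Interpolation is trilinear with periodic wrap; for rotations that
    map grid points onto grid points (e.g. C4 about a cell axis on a
    matching grid) the averaging is exact.
    """

    def __init__(self, spec: NCSConfig, grid_spec: GridSpec):
        self.spec = spec
        self.grid_spec = grid_spec
        dims = grid_spec.dims
        orth = grid_spec.cell.orthogonalization_matrix()
        frac_mat = grid_spec.cell.fractionalization_matrix()
        idx = np.indices(dims).reshape(3, -1).astype(np.float64)
        frac = idx / np.asarray(dims, dtype=np.float64)[:, None]
        r = orth @ frac
        p = orth @ np.asarray(spec.axis_point, dtype=np.float64)
        self._coords = []
        for rot in build_rotation_operators(spec):
            r_img = rot @ (r - p[:, None]) + p[:, None]
            f_img = frac_mat @ r_img
            self._coords.append(f_img * np.asarray(dims, dtype=np.float64)[:, None])

    def average(self, g: DensityGrid, region: EnvelopeMask | np.ndarray | None = None
                ) -> DensityGrid:
        return ncs_average(g, self.spec, region, _averager=self)


def ncs_average(g: DensityGrid, spec: NCSConfig,
                region: EnvelopeMask | np.ndarray | None = None,
                _averager: NCSAverager | None = None) -> DensityGrid:
    """Replace each point in the region by the mean over its n images.

    Points outside the region keep their value; ``region=None`` averages
    the whole cell.
    """
    avg = _averager or NCSAverager(spec, g.spec)
    dims = g.spec.dims
    acc = np.zeros(g.spec.n_grid)
    for coords in avg._coords:
        acc += map_coordinates(g.values, coords, order=1, mode="grid-wrap")
    acc /= spec.order
    acc = acc.reshape(dims)
    if region is None:
        out = acc
    else:
        mask = region.protein if isinstance(region, EnvelopeMask) else np.asarray(region, dtype=bool)
        out = np.where(mask, acc, g.values)
    return DensityGrid(g.spec, out)


def core_mask_from_weighted_density(
    w: DensityGrid, spec: NCSConfig, stage: int,
    solvent_fraction: float = 0.5,
) -> np.ndarray:
    """Staged core mask for NCS averaging.

    ``w`` is the Gaussian-weighted density computed at the stage's sigma
    (core_sigmas[stage-1]).  The mask is the protein-quantile threshold
    of ``w``; stages 1 and 2 are additionally restricted to a cylinder
    around the declared axis (radius sigma_stage and 2 sigma_stage
    respectively) so the core grows outward from the axis, while stage
    3 covers the whole cell and coincides with the ordinary envelope.
    This is a deliberately simple surrogate for full staged core
    growth; see the methods note.
    """
    if stage not in (1, 2, 3):
        raise ValueError("stage must be 1, 2 or 3")
    env = determine_envelope(w, solvent_fraction)
    mask = env.protein
    if stage == 3:
        return mask
    sigma = spec.core_sigmas[stage - 1]
    radius = sigma if stage == 1 else 2.0 * sigma
    dims = w.spec.dims
    orth = w.spec.cell.orthogonalization_matrix()
    idx = np.indices(dims).reshape(3, -1).astype(np.float64)
    frac = idx / np.asarray(dims, dtype=np.float64)[:, None]
    # minimum-image displacement from the axis point
    dfrac = (frac - np.asarray(spec.axis_point, dtype=np.float64)[:, None] + 0.5) % 1.0 - 0.5
    r = orth @ dfrac
    axis = np.asarray(spec.axis_direction, dtype=np.float64)
    axis = axis / np.linalg.norm(axis)
    along = axis @ r
    perp2 = np.sum(r * r, axis=0) - along * along
    cylinder = (perp2 <= radius * radius).reshape(dims)
    return mask & cylinder
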