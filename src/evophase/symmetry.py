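"""Crystallographic symmetry on the density grid.

Random starting densities and genetic edits break crystallographic
symmetry, so densities are re-symmetrized (averaged over the space-group
orbit) whenever grid values are manipulated directly.  The asymmetric
unit is realised as the set of grid points that are the lowest-index
member of their symmetry orbit; editing those points and re-expanding
reconstructs an exactly symmetric cell.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

from .grid import DensityGrid
from .lattice import GridSpec, SpaceGroupInfo, space_group

__all__ = [
    "symmetrize_density",
    "asu_indices",
    "expand_asu",
    "orbit_representatives",
]


def _check_compatible(sg: SpaceGroupInfo, dims: tuple[int, int, int]) -> None:
    n = np.asarray(dims)
    for rot, tran in sg.operators:
        t = tran * n
        if not np.allclose(t, np.round(t), atol=1e-9):
            raise ValueError(
                f"grid dims {dims} incompatible with translation {tran} of {sg.hm_symbol}"
            )
        for a in range(3):
            for b in range(3):
                if rot[a, b] != 0 and (rot[a, b] * n[a]) % n[b] != 0:
                    raise ValueError(
                        f"grid dims {dims} incompatible with rotation mixing axes "
                        f"{a},{b} in {sg.hm_symbol} (dims must match on swapped axes)"
                    )


@lru_cache(maxsize=32)
def _symmetry_permutations(symbol: str, dims: tuple[int, int, int]) -> np.ndarray:
    """For each operator, the flat source index feeding each grid point.

    Row k holds perm such that ``(op_k . g).flat = g.flat[perm]`` where
    applying op to the density samples g at the op image of each point.
    """
    sg = space_group(symbol)
    _check_compatible(sg, dims)
    n1, n2, n3 = dims
    idx = np.indices(dims).reshape(3, -1)  # integer grid coordinates
    n = np.array([n1, n2, n3])[:, None]
    perms = np.empty((sg.n_ops, n1 * n2 * n3), dtype=np.int64)
    for k, (rot, tran) in enumerate(sg.operators):
        # fractional image x' = R x + t, expressed in grid units of each axis
        img = np.empty_like(idx)
        for a in range(3):
            acc = np.full(
                idx.shape[1], int(round(tran[a] * dims[a])), dtype=np.int64
            )
            for b in range(3):
                if rot[a, b]:
                    # exact integer coefficient; divisibility checked above
                    acc += (rot[a, b] * dims[a] // dims[b]) * idx[b]
            img[a] = acc % dims[a]
        perms[k] = (img[0] * n2 + img[1]) * n3 + img[2]
    return perms


def symmetrize_density(grid: DensityGrid, sg: SpaceGroupInfo | str) -> DensityGrid:
    """Average the density over its space-group orbit (a projection)."""
    sg = space_group(sg)
    perms = _symmetry_permutations(sg.hm_symbol, grid.spec.dims)
    flat = grid.values.ravel()
    acc = np.zeros_like(flat)
    for perm in perms:
        acc += flat[perm]
    acc /= len(perms)
    return DensityGrid(grid.spec, acc.reshape(grid.spec.dims))


@lru_cache(maxsize=32)
def orbit_representatives(symbol: str, dims: tuple[int, int, int]) -> np.ndarray:
    """Flat index of the orbit representative (minimum index) per point."""
    perms = _symmetry_permutations(symbol, dims)
    return perms.min(axis=0)


def asu_indices(sg: SpaceGroupInfo | str, spec: GridSpec) -> np.ndarray:
    """Flat indices of the asymmetric-unit grid points (orbit minima)."""
    sg = space_group(sg)
    rep = orbit_representatives(sg.hm_symbol, spec.dims)
    return np.flatnonzero(rep == np.arange(rep.size))


def expand_asu(grid: DensityGrid, sg: SpaceGroupInfo | str) -> DensityGrid:
    """Propagate each orbit representative's value to its whole orbit.

    After genetic edits touch only asymmetric-unit points, this restores
    an exactly symmetric full-cell density (idempotent; the identity on
    already-symmetric maps).
    """
    sg = space_group(sg)
    rep = orbit_representatives(sg.hm_symbol, grid.spec.dims)
    values = grid.values.ravel()[rep].reshape(grid.spec.dims)
    return DensityGrid(grid.spec, values)
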