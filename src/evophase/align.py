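"""Origin and enantiomer alignment of independently reconstructed maps.

Amplitude-only data cannot distinguish density maps related by an
allowed origin shift of the space group or by inversion through a
centre, so independently reconstructed maps live in arbitrary frames.
Before any cross-map operation (crossover, averaging, scoring against a
truth map) every map is brought to a common frame by maximizing the
overlap of its protein mask with a reference mask over all allowed
transforms; the original frames are restored afterwards.

Transforms are exact grid-index permutations (translation by whole grid
steps, optional inversion through the origin); no interpolation is ever
involved, so round trips are bitwise.
"""

from __future__ import annotations

from functools import lru_cache
from typing import NamedTuple

import numpy as np

from .grid import DensityGrid
from .lattice import GridSpec, SpaceGroupInfo, space_group
from .modify import EnvelopeMask, determine_envelope, gaussian_weighted_density

__all__ = [
    "FrameTransform",
    "allowed_origin_shifts",
    "allowed_shift_grid",
    "align_to_reference",
    "apply_transform",
    "restore_origin",
    "average_aligned",
    "real_space_correlation",
]


class FrameTransform(NamedTuple):
    """x -> (-x if inverted else x) + shift, shift in fractional coords."""

    shift: tuple[float, float, float]
    inverted: bool = False

    def inverse(self) -> "FrameTransform":
        sign = -1.0 if self.inverted else 1.0
        # inverse of y = s*x + t is x = s*y - s*t (s = +/-1)
        inv_shift = tuple((-sign * t) % 1.0 for t in self.shift)
        return FrameTransform(inv_shift, self.inverted)

    def compose(self, first: "FrameTransform") -> "FrameTransform":
        """The transform 'self after first'."""
        s2 = -1.0 if self.inverted else 1.0
        shift = tuple((s2 * t1 + t2) % 1.0
                      for t1, t2 in zip(first.shift, self.shift))
        return FrameTransform(shift, self.inverted != first.inverted)

    @property
    def is_identity(self) -> bool:
        return not self.inverted and all(t % 1.0 == 0.0 for t in self.shift)


@lru_cache(maxsize=32)
def _allowed_shift_grids(symbol: str, dims: tuple[int, int, int]
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Boolean grids of allowed origin shifts, without and with inversion.

    A candidate shift t (with optional inversion) is allowed when
    conjugating every operator (R, tau) of the group by it yields an
    operator of the group again (modulo lattice translations):

        plain:    (R, tau + (I - R) t)
        inverted: (R, (I - R) t - tau)
    """
    sg = space_group(symbol)
    idx = np.indices(dims).reshape(3, -1).astype(np.float64)
    t = idx / np.asarray(dims, dtype=np.float64)[:, None]  # fractional shifts
    # group translations keyed by rotation matrix
    by_rot: dict[bytes, list[np.ndarray]] = {}
    for rot, tran in sg.operators:
        by_rot.setdefault(rot.tobytes(), []).append(tran)

    def member(tau_new: np.ndarray, taus: list[np.ndarray]) -> np.ndarray:
        ok = np.zeros(tau_new.shape[1], dtype=bool)
        for tau in taus:
            delta = (tau_new - tau[:, None]) % 1.0
            delta = np.minimum(delta, 1.0 - delta)
            ok |= np.all(delta < 1e-9, axis=0)
        return ok

    results = []
    for inverted in (False, True):
        allowed = np.ones(t.shape[1], dtype=bool)
        for rot, tran in sg.operators:
            shifted = (np.eye(3) - rot) @ t
            tau_new = (shifted + (-tran if inverted else tran)[:, None]) % 1.0
            allowed &= member(tau_new, by_rot[rot.tobytes()])
        results.append(allowed.reshape(dims))
    return results[0], results[1]


def allowed_shift_grid(sg: SpaceGroupInfo | str, spec: GridSpec,
                       inverted: bool = False) -> np.ndarray:
    """Boolean grid over shift candidates (one per grid point)."""
    sg = space_group(sg)
    plain, inv = _allowed_shift_grids(sg.hm_symbol, spec.dims)
    return inv if inverted else plain


def allowed_origin_shifts(sg: SpaceGroupInfo | str,
                          spec: GridSpec) -> list[FrameTransform]:
    """All allowed frame transforms, enumerated at grid resolution.

    Along polar axes every grid-step translation is allowed, so polar
    groups (e.g. P1) return one transform per grid point and inversion
    state.  The identity comes first; the set is a group under
    composition.
    """
    sg = space_group(sg)
    dims = spec.dims
    out = []
    for inverted in (False, True):
        mask = allowed_shift_grid(sg, spec, inverted)
        for flat in np.flatnonzero(mask.ravel()):
            i, j, k = np.unravel_index(flat, dims)
            shift = (float(i) / dims[0], float(j) / dims[1],
                     float(k) / dims[2])
            out.append(FrameTransform(shift, inverted))
    out.sort(key=lambda t: (not t.is_identity, t.inverted, t.shift))
    if not out:
        raise ValueError(f"no allowed origin shifts for {sg.hm_symbol}")
    return out


def _grid_steps(shift: tuple[float, float, float],
                dims: tuple[int, int, int]) -> tuple[int, int, int]:
    steps = []
    for t, n in zip(shift, dims):
        s = t * n
        if abs(s - round(s)) > 1e-9:
            raise ValueError(f"shift {shift} is not grid-compatible with dims {dims}")
        steps.append(int(round(s)) % n)
    return tuple(steps)


def _invert_array(values: np.ndarray) -> np.ndarray:
    """Index map i -> (-i) mod n on every axis."""
    out = values[::-1, ::-1, ::-1]
    return np.roll(out, 1, axis=(0, 1, 2))


def apply_transform(g: DensityGrid, t: FrameTransform) -> DensityGrid:
    """Apply the frame transform as an exact index permutation."""
    steps = _grid_steps(t.shift, g.spec.dims)
    values = g.values
    if t.inverted:
        values = _invert_array(values)
    values = np.roll(values, steps, axis=(0, 1, 2))
    return DensityGrid(g.spec, values.copy())


def restore_origin(g: DensityGrid, t: FrameTransform) -> DensityGrid:
    """Undo :func:`apply_transform` (bitwise round trip)."""
    return apply_transform(g, t.inverse())


def protein_mask_of(g: DensityGrid, solvent_fraction: float,
                    sigma: float = 3.0) -> EnvelopeMask:
    """The map's protein mask: weighted density thresholded by quantile."""
    w = gaussian_weighted_density(g, sigma)
    return determine_envelope(w, solvent_fraction)


def align_to_reference(
    g: DensityGrid,
    ref: DensityGrid,
    solvent_fraction: float,
    sg: SpaceGroupInfo | str = "P1",
    sigma: float = 3.0,
) -> tuple[DensityGrid, FrameTransform]:
    """Find the allowed transform best matching the reference's mask.

    The overlap objective is the protein-mask intersection count
    (equivalent to the Jaccard index here, since both masks have a
    fixed point count); it is evaluated for every allowed shift at once
    by FFT cross-correlation, for the plain and the inverted candidate.
    Ties prefer the identity, then the canonical transform order.
    """
    if g.spec.dims != ref.spec.dims:
        raise ValueError("maps must share the same grid")
    sg = space_group(sg)
    m_ref = protein_mask_of(ref, solvent_fraction, sigma).protein.astype(np.float64)
    m_g = protein_mask_of(g, solvent_fraction, sigma).protein.astype(np.float64)

    f_ref = np.fft.rfftn(m_ref)
    best: tuple[float, int, int, FrameTransform] | None = None
    dims = g.spec.dims
    for inverted in (False, True):
        cand = _invert_array(m_g) if inverted else m_g
        # overlap(s) = sum_x m_ref(x) * cand(x - s): correlate via FFT
        corr = np.fft.irfftn(f_ref * np.conj(np.fft.rfftn(cand)), s=dims, axes=(0, 1, 2))
        allowed = allowed_shift_grid(sg, g.spec, inverted)
        corr = np.where(allowed, corr, -np.inf)
        flat = int(np.argmax(corr))
        i, j, k = np.unravel_index(flat, dims)
        shift = (float(i) / dims[0], float(j) / dims[1], float(k) / dims[2])
        t = FrameTransform(shift, inverted)
        score = float(corr.ravel()[flat])
        key = (-score, 0 if t.is_identity else 1, int(inverted))
        if best is None or key < best[:3]:
            best = (*key, t)
    t = best[3]
    return apply_transform(g, t), t


def average_aligned(densities: list[DensityGrid]) -> DensityGrid:
    """Pointwise mean of maps already brought to a common frame."""
    if not densities:
        raise ValueError("no densities to average")
    spec = densities[0].spec
    acc = np.zeros(spec.dims)
    for d in densities:
        if d.spec.dims != spec.dims:
            raise ValueError("maps must share the same grid")
        acc += d.values
    return DensityGrid(spec, acc / len(densities))


def real_space_correlation(a: DensityGrid, b: DensityGrid) -> float:
    """Pearson correlation between two maps on the same grid."""
    x = a.values.ravel() - a.values.mean()
    y = b.values.ravel() - b.values.mean()
    denom = np.linalg.norm(x) * np.linalg.norm(y)
    if denom == 0.0:
        return 0.0
    return float(np.dot(x, y) / denom)
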