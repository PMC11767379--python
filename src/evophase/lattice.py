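"""Unit-cell geometry, space-group symmetry and grid construction.

All real-space work happens on a periodic grid covering the full unit
cell.  Fractional coordinates map to 0-based grid indices as x = i/n
with periodic wrap-around everywhere; the crystallographic asymmetric
unit is only ever an index subset of this grid (see :mod:`.symmetry`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import gemmi
import numpy as np

__all__ = [
    "UnitCell",
    "SpaceGroupInfo",
    "GridSpec",
    "build_grid",
    "resolution_of",
    "next_smooth",
]

#: Space groups exercised by the test suite; any Hermann-Mauguin symbol
#: gemmi knows is accepted, but grid compatibility is checked per group.
SUPPORTED_SPACE_GROUPS = ("P1", "P21212", "P212121", "P42212", "C121")


@dataclass(frozen=True)
class UnitCell:
    """Crystal unit cell: edge lengths in angstroms, angles in degrees."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("cell lengths must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0.0 < ang < 180.0:
                raise ValueError("cell angles must lie in (0, 180) degrees")
        if self.volume <= 0:
            raise ValueError("degenerate unit cell (non-positive volume)")

    @property
    def lengths(self) -> tuple[float, float, float]:
        return (self.a, self.b, self.c)

    @property
    def volume(self) -> float:
        ca, cb, cg = (np.cos(np.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        s = 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
        return self.a * self.b * self.c * np.sqrt(max(s, 0.0))

    def to_gemmi(self) -> gemmi.UnitCell:
        return gemmi.UnitCell(self.a, self.b, self.c, self.alpha, self.beta, self.gamma)

    def orthogonalization_matrix(self) -> np.ndarray:
        """3x3 matrix mapping fractional to orthogonal (angstrom) coordinates."""
        return np.array(self.to_gemmi().orth.mat.tolist())

    def fractionalization_matrix(self) -> np.ndarray:
        return np.array(self.to_gemmi().frac.mat.tolist())


@dataclass(frozen=True)
class SpaceGroupInfo:
    """Space-group operators in fractional coordinates.

    ``operators`` is a list of ``(R, t)`` pairs with integer 3x3 rotation
    matrix ``R`` and fractional translation ``t``; the set is closed as a
    group modulo lattice translations.  ``polar_axes`` flags cell axes
    along which the origin is not fixed by symmetry (continuous origin
    freedom), which matters for origin alignment of density maps.
    """

    hm_symbol: str
    operators: tuple[tuple[np.ndarray, np.ndarray], ...] = field(repr=False)
    polar_axes: tuple[bool, bool, bool]

    @classmethod
    def from_symbol(cls, symbol: str) -> "SpaceGroupInfo":
        sg = gemmi.SpaceGroup(symbol)
        ops = []
        for op in sg.operations():
            rot = np.array(op.rot, dtype=np.int64) // op.DEN
            tran = np.array(op.tran, dtype=np.float64) / op.DEN
            ops.append((rot, tran % 1.0))
        # axis e_a is polar iff every rotation leaves it fixed
        eye = np.eye(3, dtype=np.int64)
        polar = tuple(
            bool(all(np.array_equal(rot @ eye[:, a], eye[:, a]) for rot, _ in ops))
            for a in range(3)
        )
        return cls(hm_symbol=sg.hm, operators=tuple(ops), polar_axes=polar)

    @property
    def n_ops(self) -> int:
        return len(self.operators)

    def __hash__(self) -> int:  # operators are derived from the symbol
        return hash(self.hm_symbol)

    def __eq__(self, other) -> bool:
        return isinstance(other, SpaceGroupInfo) and self.hm_symbol == other.hm_symbol


@lru_cache(maxsize=None)
def _space_group(symbol: str) -> SpaceGroupInfo:
    return SpaceGroupInfo.from_symbol(symbol)


def space_group(symbol: str | SpaceGroupInfo) -> SpaceGroupInfo:
    """Resolve a Hermann-Mauguin symbol (or pass through an info object)."""
    if isinstance(symbol, SpaceGroupInfo):
        return symbol
    return _space_group(symbol)


def next_smooth(n: int) -> int:
    """Smallest integer >= n whose prime factors are all in {2, 3, 5}.

    FFT sizes with only small prime factors keep the transforms fast.
    """
    if n <= 1:
        return 1
    m = n
    while True:
        k = m
        for p in (2, 3, 5):
            while k % p == 0:
                k //= p
        if k == 1:
            return m
        m += 1


@dataclass(frozen=True)
class GridSpec:
    """Real-space sampling of the unit cell: dims, cell and resolution."""

    dims: tuple[int, int, int]
    cell: UnitCell
    d_min: float

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.dims):
            raise ValueError("grid dims must be positive")
        for n in self.dims:
            if next_smooth(n) != n:
                raise ValueError(f"grid dim {n} is not 2,3,5-smooth")

    @property
    def n_grid(self) -> int:
        n1, n2, n3 = self.dims
        return n1 * n2 * n3

    @property
    def spacing(self) -> tuple[float, float, float]:
        """Grid step along each cell axis, in angstroms."""
        return tuple(L / n for L, n in zip(self.cell.lengths, self.dims))


def build_grid(cell: UnitCell, d_min: float, oversampling: float = 3.0) -> GridSpec:
    """Choose the smallest 2,3,5-smooth grid sampling the cell at d_min.

    The step along each axis is at most ``d_min / oversampling``; the
    default threefold oversampling comfortably resolves density features
    at the resolution limit of the data.
    """
    if d_min <= 0:
        raise ValueError("d_min must be positive")
    if oversampling < 2:
        raise ValueError("oversampling must be >= 2")
    dims = tuple(
        next_smooth(int(np.ceil(L * oversampling / d_min))) for L in cell.lengths
    )
    return GridSpec(dims=dims, cell=cell, d_min=d_min)


def resolution_of(hkl, cell: UnitCell) -> float | np.ndarray:
    """Resolution d = 1/|h*| of one or many Miller indices, in angstroms."""
    h = np.asarray(hkl, dtype=np.float64)
    single = h.ndim == 1
    h = np.atleast_2d(h)
    if np.any(np.all(h == 0, axis=1)):
        raise ValueError("resolution of (0,0,0) is undefined")
    # reciprocal metric tensor G* = (A^-1)(A^-1)^T with A the
    # orthogonalization matrix; d = 1 / sqrt(h G* h)
    a_inv = cell.fractionalization_matrix()
    g_star = a_inv @ a_inv.T
    q2 = np.einsum("ij,jk,ik->i", h, g_star, h)
    d = 1.0 / np.sqrt(q2)
    return float(d[0]) if single else d
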