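"""Periodic electron-density grids and the Fourier bridge.

Conventions (fixed throughout the package):

* density values ``g(x)`` live on the full unit-cell grid, fractional
  coordinate ``x = i/n`` per axis, periodic wrap everywhere;
* structure factors are plain discrete Fourier sums,
  ``F(h) = sum_x g(x) exp(+2 pi i h.x)``, with the inverse
  ``g(x) = (1/N) sum_h F(h) exp(-2 pi i h.x)``;
* ``F(000)`` equals the grid sum; it is never part of the diffraction
  data (the beam stop makes it unmeasurable) and is carried implicitly
  as the current grid mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .lattice import GridSpec

__all__ = [
    "DensityGrid",
    "PhasedAmplitudes",
    "density_to_structure_factors",
    "structure_factors_to_density",
    "grid_transform",
    "grid_from_transform",
    "f000",
]


@dataclass
class DensityGrid:
    """Real scalar density on the unit-cell grid."""

    spec: GridSpec
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.ascontiguousarray(self.values, dtype=np.float64)
        if self.values.shape != self.spec.dims:
            raise ValueError(
                f"values shape {self.values.shape} does not match grid dims {self.spec.dims}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("density values must be finite")

    @classmethod
    def zeros(cls, spec: GridSpec) -> "DensityGrid":
        return cls(spec, np.zeros(spec.dims))

    def copy(self) -> "DensityGrid":
        return DensityGrid(self.spec, self.values.copy())

    @property
    def n_grid(self) -> int:
        return self.spec.n_grid


@dataclass
class PhasedAmplitudes:
    """Structure-factor amplitudes and phases at a list of Miller indices."""

    hkl: np.ndarray
    amplitude: np.ndarray
    phase: np.ndarray  # degrees, wrapped to [-180, 180)

    def __post_init__(self) -> None:
        self.hkl = np.asarray(self.hkl, dtype=np.int64).reshape(-1, 3)
        self.amplitude = np.asarray(self.amplitude, dtype=np.float64).ravel()
        self.phase = wrap_phase_deg(np.asarray(self.phase, dtype=np.float64).ravel())
        n = len(self.hkl)
        if len(self.amplitude) != n or len(self.phase) != n:
            raise ValueError("hkl, amplitude and phase must have equal length")
        if np.any(self.amplitude < 0):
            raise ValueError("amplitudes must be nonnegative")

    def __len__(self) -> int:
        return len(self.hkl)

    def complex_values(self) -> np.ndarray:
        return self.amplitude * np.exp(1j * np.radians(self.phase))


def wrap_phase_deg(phi: np.ndarray) -> np.ndarray:
    """Wrap phases to [-180, 180) degrees."""
    return (np.asarray(phi, dtype=np.float64) + 180.0) % 360.0 - 180.0


def f000(grid: DensityGrid) -> float:
    """The (unmeasurable) zero-order structure factor: the grid sum."""
    return float(grid.values.sum())


def grid_transform(grid: DensityGrid) -> np.ndarray:
    """Full complex structure-factor array F(h) indexed by h mod dims."""
    # ifftn carries the e^{+2 pi i} sign; scale back to a plain sum
    return np.fft.ifftn(grid.values) * grid.n_grid


def grid_from_transform(f_array: np.ndarray, spec: GridSpec) -> DensityGrid:
    """Inverse of :func:`grid_transform` (real part; F must be Hermitian)."""
    values = np.fft.fftn(f_array) / f_array.size
    return DensityGrid(spec, np.ascontiguousarray(values.real))


def _check_nyquist(hkl: np.ndarray, dims: tuple[int, int, int]) -> None:
    limits = np.array([(n - 1) // 2 for n in dims])
    if np.any(np.abs(hkl) > limits):
        bad = hkl[np.any(np.abs(hkl) > limits, axis=1)][0]
        raise ValueError(
            f"Miller index {tuple(bad)} is beyond the Nyquist limit of grid {dims}"
        )


def hkl_to_flat(hkl: np.ndarray, dims: tuple[int, int, int]) -> np.ndarray:
    """Flat index of each Miller index in the wrapped transform array."""
    hkl = np.asarray(hkl, dtype=np.int64).reshape(-1, 3)
    n1, n2, n3 = dims
    i = hkl[:, 0] % n1
    j = hkl[:, 1] % n2
    k = hkl[:, 2] % n3
    return (i * n2 + j) * n3 + k


def density_to_structure_factors(grid: DensityGrid, hkl) -> PhasedAmplitudes:
    """Structure factors of the density at the requested Miller indices.

    ``(0,0,0)`` is deliberately rejected: F(000) is reported separately
    by :func:`f000` because it never enters the phasing.
    """
    hkl = np.asarray(hkl, dtype=np.int64).reshape(-1, 3)
    if np.any(np.all(hkl == 0, axis=1)):
        raise ValueError("request F(000) via f000(), not as a reflection")
    _check_nyquist(hkl, grid.spec.dims)
    f_array = grid_transform(grid)
    f = f_array.ravel()[hkl_to_flat(hkl, grid.spec.dims)]
    return PhasedAmplitudes(hkl, np.abs(f), np.degrees(np.angle(f)))


def structure_factors_to_density(
    amps: PhasedAmplitudes, spec: GridSpec, f000: float = 0.0
) -> DensityGrid:
    """Invert phased amplitudes (plus F000) to a real density grid.

    The hkl list may cover either a Friedel half-set or the full sphere;
    missing Friedel mates are filled by conjugation.  Inconsistent mates
    (different amplitudes for h and -h) raise a data error.
    """
    _check_nyquist(amps.hkl, spec.dims)
    n = spec.n_grid
    f_array = np.zeros(spec.dims, dtype=np.complex128).ravel()
    filled = np.zeros(n, dtype=bool)
    idx = hkl_to_flat(amps.hkl, spec.dims)
    values = amps.complex_values()
    # detect duplicate/contradictory assignments, including Friedel clashes
    order = np.argsort(idx, kind="stable")
    for pos in order:
        i = idx[pos]
        if filled[i] and not np.isclose(abs(f_array[i]), abs(values[pos]), atol=1e-9 * (1 + abs(values[pos]))):
            raise ValueError("inconsistent duplicate reflection in input")
        f_array[i] = values[pos]
        filled[i] = True
    mate_idx = hkl_to_flat(-amps.hkl, spec.dims)
    mate_vals = np.conj(values)
    for pos in range(len(amps)):
        i = mate_idx[pos]
        if filled[i]:
            if not np.isclose(abs(f_array[i]), abs(mate_vals[pos]), atol=1e-9 * (1 + abs(mate_vals[pos]))):
                raise ValueError(
                    f"Friedel mates disagree for hkl {tuple(amps.hkl[pos])}"
                )
        else:
            f_array[i] = mate_vals[pos]
            filled[i] = True
    f_array[0] = f000
    return grid_from_transform(f_array.reshape(spec.dims), spec)
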