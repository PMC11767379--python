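"""Indexed diffraction amplitudes with work / free / missing bookkeeping.

Reflections carry one label each:

* ``work`` — measured, drives the phasing (99% of the measured data);
* ``free`` — measured but held out for cross-validation (about 1%);
* ``missing`` — unmeasured (typically low-angle data lost to the beam
  stop), estimated from calculated amplitudes every iteration;
* ``lowres_replaced`` — measured but below the low-resolution cutoff
  (default 15 angstroms), where recorded amplitudes are unreliable and
  calculated values are substituted, free flags included.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .lattice import UnitCell, resolution_of

__all__ = ["ReflectionSet", "assign_free_set", "unique_hkl_sphere",
           "WORK", "FREE", "MISSING", "LOWRES"]

WORK, FREE, MISSING, LOWRES = 0, 1, 2, 3
LABEL_NAMES = {WORK: "work", FREE: "free", MISSING: "missing", LOWRES: "lowres_replaced"}


@dataclass
class ReflectionSet:
    """Friedel-unique Miller indices with observed amplitudes and labels."""

    hkl: np.ndarray
    f_obs: np.ndarray
    d: np.ndarray
    label: np.ndarray
    sigma: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.hkl = np.asarray(self.hkl, dtype=np.int64).reshape(-1, 3)
        self.f_obs = np.asarray(self.f_obs, dtype=np.float64).ravel()
        self.d = np.asarray(self.d, dtype=np.float64).ravel()
        self.label = np.asarray(self.label, dtype=np.int64).ravel()
        n = len(self.hkl)
        if not (len(self.f_obs) == len(self.d) == len(self.label) == n):
            raise ValueError("field lengths disagree")
        measured = self.label != MISSING
        if np.any(self.f_obs[measured] < 0):
            raise ValueError("observed amplitudes must be nonnegative")

    @classmethod
    def from_amplitudes(
        cls,
        hkl: np.ndarray,
        f_obs: np.ndarray,
        cell: UnitCell,
        sigma: np.ndarray | None = None,
        missing: np.ndarray | None = None,
        lowres_cutoff: float | None = None,
    ) -> "ReflectionSet":
        """Build a set from raw amplitudes, applying the label rules."""
        hkl = np.asarray(hkl, dtype=np.int64).reshape(-1, 3)
        d = np.asarray(resolution_of(hkl, cell), dtype=np.float64)
        label = np.full(len(hkl), WORK, dtype=np.int64)
        if missing is not None:
            label[np.asarray(missing, dtype=bool)] = MISSING
        if lowres_cutoff is not None:
            label[d > lowres_cutoff] = LOWRES
        return cls(hkl=hkl, f_obs=np.asarray(f_obs, dtype=np.float64),
                   d=d, label=label, sigma=sigma)

    def __len__(self) -> int:
        return len(self.hkl)

    def subset(self, label: int) -> np.ndarray:
        """Positional indices of reflections carrying the given label."""
        return np.flatnonzero(self.label == label)

    @property
    def n_measured(self) -> int:
        return int(np.sum((self.label == WORK) | (self.label == FREE)))

    def relabel_lowres(self, lowres_cutoff: float) -> "ReflectionSet":
        """Return a copy with the low-resolution replacement rule applied."""
        label = self.label.copy()
        label[self.d > lowres_cutoff] = LOWRES
        keep = (self.d <= lowres_cutoff)
        label[keep & (self.label == LOWRES)] = WORK
        return ReflectionSet(self.hkl, self.f_obs, self.d, label, self.sigma)


def assign_free_set(refl: ReflectionSet, fraction: float = 0.01,
                    seed: int = 0) -> ReflectionSet:
    """Randomly hold out a fraction of the measured reflections.

    Exactly ``round(fraction * n_measured)`` reflections become free;
    missing and low-resolution-replaced reflections are never eligible.
    """
    if not 0 < fraction < 0.5:
        raise ValueError("free fraction must lie in (0, 0.5)")
    label = refl.label.copy()
    label[label == FREE] = WORK  # re-assignment starts from scratch
    eligible = np.flatnonzero(label == WORK)
    n_free = int(round(fraction * len(eligible)))
    rng = np.random.default_rng(seed)
    chosen = rng.choice(eligible, size=n_free, replace=False)
    label[chosen] = FREE
    return ReflectionSet(refl.hkl, refl.f_obs, refl.d, label, refl.sigma)


def unique_hkl_sphere(cell: UnitCell, d_min: float,
                      dims: tuple[int, int, int] | None = None) -> np.ndarray:
    """Friedel-unique Miller indices with resolution >= d_min.

    The half-sphere convention keeps h > 0, or h = 0 and k > 0, or
    h = k = 0 and l > 0.  If grid dims are given, indices beyond the
    Nyquist limit are excluded as well.
    """
    # conservative index bounds from axis lengths
    hmax = [int(np.ceil(L / d_min)) + 1 for L in cell.lengths]
    if dims is not None:
        hmax = [min(h, (n - 1) // 2) for h, n in zip(hmax, dims)]
    rng_h = np.arange(-hmax[0], hmax[0] + 1)
    rng_k = np.arange(-hmax[1], hmax[1] + 1)
    rng_l = np.arange(-hmax[2], hmax[2] + 1)
    hh, kk, ll = np.meshgrid(rng_h, rng_k, rng_l, indexing="ij")
    hkl = np.stack([hh.ravel(), kk.ravel(), ll.ravel()], axis=1)
    nonzero = np.any(hkl != 0, axis=1)
    hkl = hkl[nonzero]
    half = (hkl[:, 0] > 0) | ((hkl[:, 0] == 0) & (hkl[:, 1] > 0)) | \
           ((hkl[:, 0] == 0) & (hkl[:, 1] == 0) & (hkl[:, 2] > 0))
    hkl = hkl[half]
    d = resolution_of(hkl, cell)
    hkl = hkl[d >= d_min]
    # deterministic ordering: by resolution shell then lexicographic
    order = np.lexsort((hkl[:, 2], hkl[:, 1], hkl[:, 0]))
    return hkl[order]
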