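"""One iteration of the dual-space direct phasing cycle, plus metrics.

The cycle alternates between reciprocal space (impose observed
amplitudes, keep calculated phases) and real space (separate protein
from solvent via a Gaussian-smoothed local density, rank-match the
protein histogram to a reference, and apply hybrid input-output
negative feedback in the solvent).  Progress is tracked by the usual
crystallographic residuals:

    Rwork = sum_work | |Fobs| - lambda |Fcal| | / sum_work |Fobs|

with an analogous Rfree on the held-out set, and a mean phase error
against reference phases when a ground truth is available.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .config import PhasingConfig
from .grid import DensityGrid
from .lattice import GridSpec, SpaceGroupInfo, space_group
from .reflections import FREE, LOWRES, MISSING, WORK, ReflectionSet

__all__ = [
    "ScaleModel",
    "EnvelopeMask",
    "ReferenceHistogram",
    "MetricsRecord",
    "ProjectionPlan",
    "compute_scale",
    "r_factor",
    "mean_phase_error",
    "fill_missing_amplitudes",
    "amplitude_projection",
    "gaussian_weighted_density",
    "sigma0_schedule",
    "determine_envelope",
    "histogram_match",
    "hio_step",
    "solvent_flatten_step",
    "PhasingState",
    "DirectPhaser",
    "phasing_cycle",
]


# --------------------------------------------------------------------------
# small value types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ScaleModel:
    """Multiplicative scale lambda putting |Fcal| on the observation scale."""

    lam: float

    def __post_init__(self) -> None:
        if not self.lam > 0:
            raise ValueError("scale factor must be positive")


@dataclass
class EnvelopeMask:
    """Boolean protein/solvent partition of the grid (True = protein)."""

    protein: np.ndarray
    solvent_fraction: float

    def __post_init__(self) -> None:
        self.protein = np.asarray(self.protein, dtype=bool)

    @property
    def n_protein(self) -> int:
        return int(self.protein.sum())

    @property
    def solvent(self) -> np.ndarray:
        return ~self.protein


class ReferenceHistogram:
    """Quantile function of protein-region density values.

    Stored as a sorted sample; the quantile at probability p is linear
    interpolation between sample plotting positions (k - 0.5) / n.
    """

    def __init__(self, sample: np.ndarray):
        sample = np.sort(np.asarray(sample, dtype=np.float64).ravel())
        if sample.size == 0:
            raise ValueError("reference histogram needs at least one value")
        if not np.all(np.isfinite(sample)):
            raise ValueError("reference histogram values must be finite")
        self.sample = sample
        self._matched_cache: dict[int, np.ndarray] = {}

    def __len__(self) -> int:
        return len(self.sample)

    def quantile(self, p: np.ndarray) -> np.ndarray:
        n = len(self.sample)
        positions = (np.arange(n) + 0.5) / n
        return np.interp(p, positions, self.sample)

    def matched_values(self, n_points: int) -> np.ndarray:
        """Sorted target values for a region of n_points (cached)."""
        cached = self._matched_cache.get(n_points)
        if cached is None:
            cached = self.quantile((np.arange(n_points) + 0.5) / n_points)
            if len(self._matched_cache) > 8:
                self._matched_cache.clear()
            self._matched_cache[n_points] = cached
        return cached

    def subsample(self, max_size: int, seed: int = 0) -> "ReferenceHistogram":
        if len(self.sample) <= max_size:
            return self
        rng = np.random.default_rng(seed)
        pick = rng.choice(len(self.sample), size=max_size, replace=False)
        return ReferenceHistogram(self.sample[pick])


@dataclass
class MetricsRecord:
    iteration: int
    rwork: float
    rfree: float
    sigma0: float
    elite: bool = False
    phase_error: float | None = None


# --------------------------------------------------------------------------
# reciprocal-space metrics
# --------------------------------------------------------------------------

def compute_scale(f_obs: np.ndarray, f_cal: np.ndarray, subset: np.ndarray) -> ScaleModel:
    """Least-squares amplitude scale on the given subset.

    lambda = sum |Fobs||Fcal| / sum |Fcal|^2, minimising
    sum (|Fobs| - lambda |Fcal|)^2 over the subset.
    """
    fo = np.asarray(f_obs, dtype=np.float64)[subset]
    fc = np.asarray(f_cal, dtype=np.float64)[subset]
    if fo.size == 0:
        raise ValueError("scale subset is empty")
    denom = float(np.sum(fc * fc))
    if denom == 0.0:
        raise ZeroDivisionError("all calculated amplitudes are zero")
    return ScaleModel(float(np.sum(fo * fc)) / denom)


def r_factor(f_obs: np.ndarray, f_cal: np.ndarray, scale: ScaleModel,
             subset: np.ndarray) -> float:
    """Normalized amplitude residual on a reflection subset."""
    fo = np.asarray(f_obs, dtype=np.float64)[subset]
    fc = np.asarray(f_cal, dtype=np.float64)[subset]
    if fo.size == 0:
        raise ValueError("R-factor subset is empty")
    denom = float(np.sum(fo))
    if denom == 0.0:
        raise ZeroDivisionError("sum of observed amplitudes is zero")
    return float(np.sum(np.abs(fo - scale.lam * fc))) / denom


def mean_phase_error(phi_true: np.ndarray, phi_cal: np.ndarray,
                     subset: np.ndarray | None = None) -> float:
    """Unweighted mean of the wrapped phase difference, in degrees.

    Each term is arccos(cos(phi_true - phi_cal)), i.e. the angular
    distance on the circle, so the result lies in [0, 180].
    """
    phi_true = np.asarray(phi_true, dtype=np.float64)
    phi_cal = np.asarray(phi_cal, dtype=np.float64)
    if subset is not None:
        phi_true = phi_true[subset]
        phi_cal = phi_cal[subset]
    if phi_true.size == 0:
        raise ValueError("phase-error subset is empty")
    delta = np.radians(phi_true - phi_cal)
    return float(np.degrees(np.mean(np.arccos(np.clip(np.cos(delta), -1.0, 1.0)))))


def fill_missing_amplitudes(f_obs: np.ndarray, f_cal: np.ndarray,
                            work: np.ndarray, targets: np.ndarray) -> np.ndarray:
    """Estimate unmeasured amplitudes from calculated ones.

    |Fmiss(h)| = (sum_work |Fobs| / sum_work |Fcal|) * |Fcal(h)|
    for each target reflection (beam-stop gaps and low-resolution
    replacements alike).
    """
    fo = np.asarray(f_obs, dtype=np.float64)
    fc = np.asarray(f_cal, dtype=np.float64)
    denom = float(np.sum(fc[work]))
    if denom == 0.0:
        raise ZeroDivisionError("sum of calculated work amplitudes is zero")
    ratio = float(np.sum(fo[work])) / denom
    return ratio * fc[targets]


# --------------------------------------------------------------------------
# amplitude projection
# --------------------------------------------------------------------------

class ProjectionPlan:
    """Precomputed mapping from grid frequencies to reflection records.

    The reflection file stores one Friedel-unique record per reflection;
    on the transform grid every symmetry mate and Friedel mate of that
    record must receive the same amplitude.  The plan also low-passes
    the transform: in-band frequencies not covered by any record are
    treated as unmeasured (filled from calculated values), frequencies
    beyond the resolution limit of the data are zeroed.

    The hot path works on the real-FFT half-spectrum: amplitude
    replacement is Friedel-symmetric, so scaling the half-spectrum with
    real factors is exactly equivalent to scaling the full cube.
    """

    def __init__(self, refl: ReflectionSet, spec: GridSpec,
                 sg: SpaceGroupInfo | str = "P1"):
        sg = space_group(sg)
        self.spec = spec
        self.refl = refl
        dims = spec.dims
        n1, n2, n3 = dims
        half3 = n3 // 2 + 1
        self.half_shape = (n1, n2, half3)
        n_half = n1 * n2 * half3

        def half_flat(hkl: np.ndarray) -> np.ndarray:
            """Half-spectrum flat index, or -1 where l wraps past n3//2."""
            i = hkl[:, 0] % n1
            j = hkl[:, 1] % n2
            k = hkl[:, 2] % n3
            ok = k < half3
            idx = (i * n2 + j) * half3 + k
            return np.where(ok, idx, -1)

        refl_id = np.full(n_half, -1, dtype=np.int64)
        ids = np.arange(len(refl))
        for rot, _ in sg.operators:
            mates = refl.hkl @ rot  # row-vector action: h' = h R
            for sign in (1, -1):
                idx = half_flat(sign * mates)
                good = idx >= 0
                refl_id[idx[good]] = ids[good]
        refl_id[0] = -1  # F000 never belongs to the data
        self.refl_id = refl_id

        # representative half-spectrum index of each unique reflection
        rep = half_flat(refl.hkl)
        mate = half_flat(-refl.hkl)
        self.rep_flat = np.where(rep >= 0, rep, mate)
        if np.any(self.rep_flat < 0):
            raise ValueError("reflection beyond the grid Nyquist limit")

        # band mask: resolution of every half-spectrum frequency
        f1 = np.fft.fftfreq(n1, 1.0 / n1)
        f2 = np.fft.fftfreq(n2, 1.0 / n2)
        f3 = np.arange(half3, dtype=np.float64)
        hh, kk, ll = np.meshgrid(f1, f2, f3, indexing="ij")
        hkl_all = np.stack([hh.ravel(), kk.ravel(), ll.ravel()], axis=1)
        a_inv = spec.cell.fractionalization_matrix()
        g_star = a_inv @ a_inv.T
        q2 = np.einsum("ij,jk,ik->i", hkl_all, g_star, hkl_all)
        in_band = q2 <= (1.0 / spec.d_min) ** 2 + 1e-12
        in_band[0] = True
        # flat index views used on the hot path
        self.mapped_idx = np.flatnonzero(refl_id >= 0)
        self.mapped_refl = refl_id[self.mapped_idx]
        unlisted = in_band & (refl_id < 0)
        unlisted[0] = False
        self.fill_idx = np.flatnonzero(unlisted)
        self.zero_idx = np.flatnonzero(~in_band)


def amplitude_projection(
    grid: DensityGrid, refl: ReflectionSet, plan: ProjectionPlan
) -> tuple[DensityGrid, ScaleModel, float, float]:
    """Impose observed amplitudes on the density's transform.

    Work reflections get |Fobs| / lambda (internal scale), missing and
    low-resolution reflections get the calculated-amplitude estimate,
    free reflections keep their calculated amplitude and phase exactly.
    Returns the projected density together with this iteration's scale
    and the Rwork / Rfree computed before replacement.
    """
    f_half = np.fft.rfftn(grid.values)
    f_array = f_half.ravel()
    amp = np.abs(f_array)

    f_cal = amp[plan.rep_flat]
    work = refl.subset(WORK)
    free = refl.subset(FREE)
    scale = compute_scale(refl.f_obs, f_cal, work)
    rwork = r_factor(refl.f_obs, f_cal, scale, work)
    rfree = r_factor(refl.f_obs, f_cal, scale, free) if free.size else float("nan")

    denom = float(np.sum(f_cal[work]))
    if denom == 0.0:
        raise ZeroDivisionError("sum of calculated work amplitudes is zero")
    fill_ratio = float(np.sum(refl.f_obs[work])) / denom

    # per-unique-reflection target amplitude on the internal (grid) scale
    target_unique = f_cal.copy()
    target_unique[work] = refl.f_obs[work] / scale.lam
    for lab in (MISSING, LOWRES):
        sel = refl.subset(lab)
        target_unique[sel] = fill_ratio * f_cal[sel] / scale.lam
    # free reflections keep f_cal: already in target_unique

    target = amp.copy()
    target[plan.mapped_idx] = target_unique[plan.mapped_refl]
    target[plan.fill_idx] = fill_ratio * amp[plan.fill_idx] / scale.lam
    target[plan.zero_idx] = 0.0
    target[0] = amp[0]  # F000 carried over, never replaced by observation

    safe = np.maximum(amp, 1e-300)
    new_f = f_array * (target / safe)
    zero_amp = (amp <= 1e-300) & (target > 0)
    if zero_amp.any():
        new_f[zero_amp] = target[zero_amp]  # undefined phase: take 0
    new_f[0] = f_array[0]
    values = np.fft.irfftn(new_f.reshape(plan.half_shape), s=grid.spec.dims, axes=(0, 1, 2))
    return DensityGrid(grid.spec, values), scale, rwork, rfree


# --------------------------------------------------------------------------
# real-space operators
# --------------------------------------------------------------------------

@lru_cache(maxsize=8)
def _min_image_r2(spec_key: tuple) -> np.ndarray:
    dims, cell_params = spec_key
    from .lattice import UnitCell
    cell = UnitCell(*cell_params)
    frac = [
        (np.arange(d) / d + 0.5) % 1.0 - 0.5  # minimum-image fractional offset
        for d in dims
    ]
    fx, fy, fz = np.meshgrid(*frac, indexing="ij")
    orth = cell.orthogonalization_matrix()
    rx = orth[0, 0] * fx + orth[0, 1] * fy + orth[0, 2] * fz
    ry = orth[1, 0] * fx + orth[1, 1] * fy + orth[1, 2] * fz
    rz = orth[2, 0] * fx + orth[2, 1] * fy + orth[2, 2] * fz
    return rx * rx + ry * ry + rz * rz


def _spec_key(spec: GridSpec) -> tuple:
    c = spec.cell
    return (spec.dims, (c.a, c.b, c.c, c.alpha, c.beta, c.gamma))


_KERNEL_CACHE: dict[tuple, np.ndarray] = {}


def gaussian_weighted_density(grid: DensityGrid, sigma0: float) -> DensityGrid:
    """Periodic Gaussian-weighted local average of the density.

    w_i = sum_j exp(-r_ij^2 / (2 sigma0^2)) g_j with r_ij the
    minimum-image inter-grid distance in angstroms; evaluated as a
    circular convolution via FFT.  The kernel is deliberately left
    unnormalized; only the ranking of w values matters downstream.
    """
    if sigma0 <= 0:
        raise ValueError("sigma0 must be positive")
    key = (_spec_key(grid.spec), round(float(sigma0), 12))
    kernel_f = _KERNEL_CACHE.get(key)
    if kernel_f is None:
        r2 = _min_image_r2(_spec_key(grid.spec))
        kernel = np.exp(-r2 / (2.0 * sigma0 * sigma0))
        kernel_f = np.fft.rfftn(kernel)
        if len(_KERNEL_CACHE) > 64:
            _KERNEL_CACHE.clear()
        _KERNEL_CACHE[key] = kernel_f
    w = np.fft.irfftn(np.fft.rfftn(grid.values) * kernel_f, s=grid.spec.dims, axes=(0, 1, 2))
    return DensityGrid(grid.spec, w)


def sigma0_schedule(iteration: int, cfg: PhasingConfig) -> float:
    """Linearly ramp the averaging radius from sigma_start to sigma_end.

    The ramp spans the first ``sigma_ramp_fraction`` of max_iter and the
    radius stays at sigma_end afterwards; a large early radius tolerates
    the noisy start, the tighter final radius sharpens the envelope.
    """
    if iteration < 0:
        raise ValueError("iteration must be nonnegative")
    ramp_end = cfg.sigma_ramp_fraction * cfg.max_iter
    if ramp_end <= 0 or iteration >= ramp_end:
        return cfg.sigma_end
    t = iteration / ramp_end
    return cfg.sigma_start + t * (cfg.sigma_end - cfg.sigma_start)


def determine_envelope(w: DensityGrid, solvent_fraction: float) -> EnvelopeMask:
    """Partition the cell by thresholding the weighted density.

    The round((1 - solvent_fraction) * N) points with the highest w are
    protein; ties are resolved in stable ascending index order, lower
    index winning the protein label.
    """
    if not 0.0 < solvent_fraction < 1.0:
        raise ValueError("solvent_fraction must lie in (0, 1)")
    flat = w.values.ravel()
    n = flat.size
    n_protein = int(round((1.0 - solvent_fraction) * n))
    mask = np.zeros(n, dtype=bool)
    if n_protein >= n:
        mask[:] = True
    elif n_protein > 0:
        # partition for speed; resolve threshold ties by ascending index
        part = np.argpartition(-flat, n_protein - 1)
        threshold = flat[part[n_protein - 1]]
        mask[flat > threshold] = True
        deficit = n_protein - int(mask.sum())
        if deficit > 0:
            ties = np.flatnonzero(flat == threshold)
            mask[ties[:deficit]] = True
    return EnvelopeMask(mask.reshape(w.spec.dims), solvent_fraction)


def histogram_match(g: DensityGrid, mask: EnvelopeMask,
                    ref: ReferenceHistogram) -> DensityGrid:
    """Rank-transform protein-region values onto the reference histogram.

    The k-th smallest protein value becomes the reference quantile at
    plotting position (k - 0.5) / n; ties are broken by index order so
    the map is deterministic and rank-preserving.  Solvent values are
    untouched.
    """
    sel = mask.protein.ravel()
    n_p = int(sel.sum())
    if n_p == 0:
        raise ValueError("protein region is empty")
    out = g.values.ravel().copy()
    vals = out[sel]
    order = np.argsort(vals, kind="stable")
    matched = np.empty(n_p)
    matched[order] = ref.matched_values(n_p)
    out[sel] = matched
    return DensityGrid(g.spec, out.reshape(g.spec.dims))


def hio_step(g_prev: DensityGrid, g_proj: DensityGrid,
             g_protein_mod: DensityGrid, mask: EnvelopeMask,
             beta: float) -> DensityGrid:
    """Hybrid input-output update: feedback only in the solvent.

    Protein points take the histogram-matched projected density;
    solvent points take g_prev - beta * g_proj, the negative feedback
    that steers the solvent toward constancy without hard clamping.
    """
    if not 0.0 <= beta <= 1.0:
        raise ValueError("beta must lie in [0, 1]")
    for other in (g_proj, g_protein_mod):
        if other.spec.dims != g_prev.spec.dims:
            raise ValueError("grids must share the same spec")
    out = np.where(mask.protein, g_protein_mod.values,
                   g_prev.values - beta * g_proj.values)
    return DensityGrid(g_prev.spec, out)


def solvent_flatten_step(g_proj: DensityGrid, mask: EnvelopeMask,
                         g_protein_mod: DensityGrid | None = None) -> DensityGrid:
    """Classical solvent flattening: solvent set to its mean value."""
    solvent = mask.solvent
    if not solvent.any():
        raise ValueError("solvent region is empty")
    protein_vals = (g_protein_mod or g_proj).values
    mean_solvent = float(g_proj.values[solvent].mean())
    out = np.where(mask.protein, protein_vals, mean_solvent)
    return DensityGrid(g_proj.spec, out)


# --------------------------------------------------------------------------
# the full cycle
# --------------------------------------------------------------------------

@dataclass
class PhasingState:
    """Per-reconstruction state threaded through phasing cycles."""

    grid: DensityGrid
    iteration: int = 0
    mode: str = "hio"  # or "flatten"
    metrics: list[MetricsRecord] = field(default_factory=list)
    last_mask: EnvelopeMask | None = None

    @property
    def rwork_trace(self) -> np.ndarray:
        return np.array([m.rwork for m in self.metrics])

    @property
    def rfree_trace(self) -> np.ndarray:
        return np.array([m.rfree for m in self.metrics])


class DirectPhaser:
    """Bundles the data-dependent machinery of the phasing cycle.

    Holds the reflection data, the projection plan, the reference
    histogram and the configuration so a cycle is a pure function of
    the per-reconstruction state.
    """

    def __init__(self, refl: ReflectionSet, spec: GridSpec,
                 cfg: PhasingConfig, ref_hist: ReferenceHistogram,
                 sg: SpaceGroupInfo | str = "P1",
                 ncs_averager=None):
        self.refl = refl
        self.spec = spec
        self.cfg = cfg
        self.ref_hist = ref_hist
        self.sg = space_group(sg)
        self.plan = ProjectionPlan(refl, spec, self.sg)
        self.ncs_averager = ncs_averager

    def cycle(self, state: PhasingState) -> PhasingState:
        """Advance one dual-space iteration (projection -> envelope ->
        histogram matching -> HIO or solvent flattening)."""
        cfg = self.cfg
        sigma0 = (cfg.sigma_end if state.mode == "flatten"
                  else sigma0_schedule(state.iteration, cfg))
        g_proj, scale, rwork, rfree = amplitude_projection(
            state.grid, self.refl, self.plan)
        w = gaussian_weighted_density(g_proj, sigma0)
        mask = determine_envelope(w, cfg.solvent_fraction)
        if self.ncs_averager is not None:
            g_proj = self.ncs_averager.average(g_proj, mask)
        if state.mode == "flatten" and not cfg.flatten_histogram_match:
            g_protein = g_proj
        else:
            g_protein = histogram_match(g_proj, mask, self.ref_hist)
        if state.mode == "flatten":
            g_next = solvent_flatten_step(g_proj, mask, g_protein)
        else:
            g_next = hio_step(state.grid, g_proj, g_protein, mask, cfg.beta)
        metrics = state.metrics + [MetricsRecord(
            iteration=state.iteration, rwork=rwork, rfree=rfree, sigma0=sigma0)]
        return PhasingState(grid=g_next, iteration=state.iteration + 1,
                            mode=state.mode, metrics=metrics, last_mask=mask)


def phasing_cycle(state: PhasingState, phaser: DirectPhaser) -> PhasingState:
    """Functional alias for :meth:`DirectPhaser.cycle`."""
    return phaser.cycle(state)
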