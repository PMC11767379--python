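"""Self-contained toy crystals for building and testing the phasing stack.

A toy crystal is a sum of Gaussian blobs placed inside one contiguous
sub-box of the cell (so the protein region is connected), symmetrized
over the space group, band-limited to the resolution of the synthetic
data and normalized so protein density lives on the [0, 1] scale the
mutation operator assumes.  Amplitude-only data are derived from the
truth map, with optional multiplicative log-normal noise and a
simulated beam-stop gap at low scattering angles.  The reference
density histogram is sampled from the truth protein region, standing in
for the similar-resolution reference structure a real run would use.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import DensityGrid, PhasedAmplitudes, density_to_structure_factors
from .lattice import GridSpec, UnitCell, build_grid, space_group
from .modify import EnvelopeMask, ReferenceHistogram, determine_envelope, \
    gaussian_weighted_density
from .reflections import MISSING, ReflectionSet, unique_hkl_sphere
from .symmetry import symmetrize_density

__all__ = ["ToyCrystalSpec", "ToyCrystalBundle", "generate_toy_crystal",
           "reference_histogram_from_density", "TOY_PRESETS"]


@dataclass(frozen=True)
class ToyCrystalSpec:
    """Recipe for one synthetic crystal."""

    cell: UnitCell = field(default_factory=lambda: UnitCell(20.0, 20.0, 20.0))
    space_group: str = "P1"
    d_min: float = 2.0
    oversampling: float = 3.0
    n_blobs: int = 24
    blob_width: tuple[float, float] = (1.0, 1.8)  # Gaussian sigma range (A)
    solvent_fraction: float = 0.72
    noise: float = 0.0           # fractional amplitude noise (log-normal sigma)
    beamstop_d: float = 15.0     # reflections with d above this are unmeasured
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.3 <= self.solvent_fraction <= 0.9:
            raise ValueError("solvent_fraction must lie in [0.3, 0.9]")
        if self.n_blobs < 1:
            raise ValueError("n_blobs must be >= 1")
        if self.noise < 0:
            raise ValueError("noise must be nonnegative")


@dataclass
class ToyCrystalBundle:
    """Everything a test or a run needs about one toy crystal."""

    spec: ToyCrystalSpec
    grid_spec: GridSpec
    truth: DensityGrid
    truth_phases: PhasedAmplitudes
    reflections: ReflectionSet
    histogram: ReferenceHistogram
    truth_mask: EnvelopeMask


def _blob_density(grid_spec: GridSpec, centers: np.ndarray, widths: np.ndarray,
                  heights: np.ndarray) -> np.ndarray:
    dims = grid_spec.dims
    orth = grid_spec.cell.orthogonalization_matrix()
    idx = np.indices(dims).reshape(3, -1).astype(np.float64)
    frac = idx / np.asarray(dims, dtype=np.float64)[:, None]
    values = np.zeros(frac.shape[1])
    for c, w, h in zip(centers, widths, heights):
        dfrac = (frac - c[:, None] + 0.5) % 1.0 - 0.5  # minimum image
        r = orth @ dfrac
        r2 = np.sum(r * r, axis=0)
        values += h * np.exp(-r2 / (2.0 * w * w))
    return values.reshape(dims)


def generate_toy_crystal(spec: ToyCrystalSpec) -> ToyCrystalBundle:
    """Build a toy crystal bundle (deterministic for a given spec).

    The truth density is exactly band-limited to d_min, so imposing the
    noiseless amplitudes on the truth map is the identity: the truth is
    a genuine fixed point of the amplitude projection.
    """
    rng = np.random.default_rng(spec.seed)
    grid_spec = build_grid(spec.cell, spec.d_min, spec.oversampling)
    sg = space_group(spec.space_group)

    # blob centers in one contiguous sub-box so the protein is connected;
    # the box edge tracks the requested protein volume fraction
    protein_fraction = 1.0 - spec.solvent_fraction
    edge = min(0.8, (1.2 * protein_fraction) ** (1.0 / 3.0))
    origin = np.full(3, 0.05)
    centers = origin + rng.random((spec.n_blobs, 3)) * edge
    widths = rng.uniform(*spec.blob_width, size=spec.n_blobs)
    heights = rng.uniform(0.5, 1.0, size=spec.n_blobs)

    raw = DensityGrid(grid_spec, _blob_density(grid_spec, centers, widths, heights))
    if sg.n_ops > 1:
        raw = symmetrize_density(raw, sg)

    # Refine the blob map toward a physical crystal: band-limited to the
    # data resolution AND flat (zero) bulk solvent outside a fixed
    # envelope.  The two constraints cannot be met exactly at once (that
    # over-determination is what makes phases recoverable), so a few
    # hundred alternating projections leave a sub-percent solvent ripple.
    a_inv = spec.cell.fractionalization_matrix()
    g_star = a_inv @ a_inv.T
    freqs = [np.fft.fftfreq(d, 1.0 / d) for d in grid_spec.dims]
    hh, kk, ll = np.meshgrid(*freqs, indexing="ij")
    hkl_all = np.stack([hh.ravel(), kk.ravel(), ll.ravel()], axis=1)
    q2 = np.einsum("ij,jk,ik->i", hkl_all, g_star, hkl_all).reshape(grid_spec.dims)
    in_band = q2 <= (1.0 / spec.d_min) ** 2 + 1e-12

    def band_limit(v: np.ndarray) -> np.ndarray:
        f = np.fft.ifftn(v)
        f[~in_band] = 0.0
        return np.fft.fftn(f).real

    values = band_limit(raw.values)

    def envelope_of(v: np.ndarray) -> np.ndarray:
        w = gaussian_weighted_density(DensityGrid(grid_spec, v), 3.0)
        return determine_envelope(w, spec.solvent_fraction).protein

    # jointly refine density and envelope until the envelope recomputed
    # from the refined map is the envelope the map was refined against
    protein0 = envelope_of(values)
    for _ in range(12):
        for _ in range(50):
            values = np.where(protein0, values, 0.0)
            values = band_limit(values)
        new_mask = envelope_of(values)
        stable = bool(np.all(new_mask == protein0))
        protein0 = new_mask
        if stable:
            break
    for _ in range(200):
        values = np.where(protein0, values, 0.0)
        values = band_limit(values)
    peak = float(values.max())
    if peak <= 0:
        raise ValueError("degenerate toy crystal: empty density")
    truth = DensityGrid(grid_spec, values / peak)
    if sg.n_ops > 1:
        truth = symmetrize_density(truth, sg)
    truth_mask = EnvelopeMask(protein0, spec.solvent_fraction)

    hkl = unique_hkl_sphere(spec.cell, spec.d_min, grid_spec.dims)
    phased = density_to_structure_factors(truth, hkl)
    f_obs = phased.amplitude.copy()
    if spec.noise > 0:
        f_obs = f_obs * rng.lognormal(mean=0.0, sigma=spec.noise, size=len(f_obs))
    refl = ReflectionSet.from_amplitudes(hkl, f_obs, spec.cell)
    missing = refl.d > spec.beamstop_d
    refl.label[missing] = MISSING

    hist = reference_histogram_from_density(truth, truth_mask)
    return ToyCrystalBundle(
        spec=spec, grid_spec=grid_spec, truth=truth, truth_phases=phased,
        reflections=refl, histogram=hist, truth_mask=truth_mask,
    )


def reference_histogram_from_density(g: DensityGrid, mask: EnvelopeMask,
                                     max_size: int = 100_000,
                                     seed: int = 0) -> ReferenceHistogram:
    """Protein-region density values as a reference histogram."""
    vals = g.values[mask.protein]
    if vals.size == 0:
        raise ValueError("protein region is empty")
    hist = ReferenceHistogram(vals)
    return hist.subsample(max_size, seed=seed)


def toy_run_config(seed: int = 0, workers: int = 1,
                   ga_enabled: bool = True):
    """Desk-scale run protocol for the toy crystal.

    Population 16, GA every 50 iterations, at most 3000 dual-space
    iterations; the elite windows are half the full-scale defaults
    because convergence on the toy is correspondingly faster.  The
    solvent estimate (0.70) deliberately underestimates the true toy
    solvent content (0.72), mirroring the recommended protocol.

    Elite detection uses the Rwork windows only: the toy's amplitudes
    are noiseless, so Rfree sits at its floor from early on and a
    further sliding-window drop in Rfree is structurally impossible
    (the Rfree gate is meant for noisy data, where Rfree tracks Rwork).
    """
    from .config import GAConfig, PhasingConfig, RunConfig

    return RunConfig(
        phasing=PhasingConfig(solvent_fraction=0.70, max_iter=3000),
        ga=GAConfig(population_size=16, ga_interval=50,
                    window_recent=50, window_past=50, window_gap=50,
                    elite_use_rfree=False, enabled=ga_enabled),
        seed=seed, workers=workers,
    )


#: Named study conditions for the end-to-end experiments.
TOY_PRESETS: dict[str, ToyCrystalSpec] = {
    # desk-scale benchmark: high solvent content, noiseless amplitudes
    "toy": ToyCrystalSpec(),
    # low solvent content without NCS: generally not solvable, kept as a
    # documented negative control
    "hard": ToyCrystalSpec(solvent_fraction=0.45, n_blobs=48),
    # small orthorhombic crystal exercising crystallographic symmetry
    "p212121": ToyCrystalSpec(cell=UnitCell(24.0, 24.0, 24.0),
                              space_group="P212121", n_blobs=8,
                              solvent_fraction=0.75),
}
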