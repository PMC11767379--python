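# Methods

## The phase problem and the model behind the package

A crystal diffraction experiment measures structure-factor amplitudes
|F(h)| on a reciprocal lattice; the phases are lost. The electron
density g and the structure factors are a Fourier pair, so recovering g
from amplitudes alone requires extra real-space knowledge. This package
uses the two classical constraints for macromolecular crystals:

* **Bulk solvent is flat.** A large fraction of the cell (ideally
  above ~65%) is disordered solvent of constant density. Counting
  degrees of freedom: a band-limited map has about as many free
  parameters as there are reflections; demanding constancy on most of
  the cell over-determines the problem, which is exactly what makes the
  lost phases recoverable.
* **Protein density has a universal histogram.** At a given resolution
  the distribution of density values inside the protein region is
  nearly structure-independent, so the protein region can be
  rank-transformed onto a reference histogram.

Neither constraint identifies the map uniquely: any map related by an
allowed origin shift of the space group, or by inversion through a
centre (the enantiomer ambiguity), has identical amplitudes. All map
comparisons in the package are therefore made after explicit alignment
over those equivalences.

## The dual-space cycle

One iteration, from current density g_k on the full unit-cell grid:

1. **Amplitude projection.** F_cal = FFT(g_k). The scale
   λ = Σ|Fobs||Fcal| / Σ|Fcal|² is a least-squares fit on the working
   set, recomputed every iteration. Rwork and Rfree
   (R = Σ‖Fobs| − λ|Fcal‖ / Σ|Fobs|) are recorded *before* amplitude
   replacement. Work reflections then receive |Fobs|/λ; unmeasured and
   low-resolution-replaced reflections receive
   (Σ_work|Fobs| / Σ_work|Fcal|)·|Fcal|/λ; free reflections keep their
   calculated amplitude; frequencies beyond the resolution of the data
   are zeroed (low-pass); F(000) is carried as the current grid mean
   and never imposed. Phases are always preserved. Inverse FFT gives
   g′_k.
2. **Envelope.** w = g′ ⊛ exp(−r²/2σ₀²) (periodic FFT convolution,
   minimum-image distances, kernel unnormalized — only the ranking of w
   matters). The round((1 − solvent_fraction)·N) points with the
   largest w are protein; ties break by ascending index.
3. **Histogram matching.** Protein values are rank-mapped onto the
   reference quantiles at plotting positions (k − 0.5)/n.
4. **Update.** HIO mode: protein points take the histogram-matched g′;
   solvent points take g_k − β·g′_k. Flatten mode (used for the final
   polishing cycles): solvent points take the solvent mean of g′
   instead.

With per-iteration NCS averaging enabled, g′ is averaged over the
declared rotation images (within the current protein region) after the
envelope is determined and before histogram matching, matching the
stated order "HIO density modification, then NCS averaging and
histogram matching".

### Why Rwork churns while the solution is held

The flat-solvent and band-limit constraints cannot be satisfied
simultaneously and exactly (the over-determination above), so even the
true map carries a sub-percent solvent ripple. HIO's negative feedback
keeps injecting −β·ripple each cycle; the map hovers around the
solution with Rwork at a few times the ripple scale rather than
converging to a point. This is by design — the same agitation is what
lets HIO escape stagnation. The error-reduction variant (solvent
flattening) is contractive and pins a solution; that is why converged
runs are finished with 200 flattening cycles. Rfree can sit *below*
Rwork in this package: free amplitudes are never reset during
projection, so they relax smoothly under the real-space constraints,
while work amplitudes are hard-reset each cycle and re-perturbed by the
real-space step.

In P1 (and along polar axes generally) the origin is unconstrained, and
the hovering map slowly random-walks through equivalent origins. This
is invisible to R factors and harmless; correlations and phase errors
are always computed after alignment.

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| β | 0.7 | HIO feedback strength; standard middle of the usual (0.5–1.0) range |
| σ₀ schedule | 4.0 → 3.0 Å | Gaussian averaging radius, linear ramp over the first 60% of max_iter; large early radius tolerates chaotic starts, small late radius sharpens the envelope |
| solvent_fraction | user's estimate | deliberately underestimate (e.g. 0.70 for a true 0.72) so the protein region surely covers the protein |
| lowres_cutoff | 15 Å | measured amplitudes beyond this d-spacing are unreliable and replaced by calculated estimates, free flags included |
| free_fraction | 0.01 | held-out cross-validation set |
| oversampling | 3 | grid step ≤ d_min/3 per axis; 2,3,5-smooth dims for fast FFTs |
| population_size | 100 (16 in the desk-scale preset) | independent reconstructions |
| ga_interval | 100 (50) | dual-space iterations between genetic operations |
| crossover | 50% in 10 segments | contiguous runs in flattened asymmetric-unit index order, non-overlapping, start positions uniform |
| mutation | 1%, uniform (0,1) | density values live on a normalized scale with the reference histogram inside [0,1], so uniform(0,1) draws are commensurate |
| elite_drop_threshold | 0.02 | sliding-window mean drop that flags convergence |
| elite windows | 100/100/100 (50/50/50) | recent/gap/past window lengths; scaled with ga_interval |
| flatten_cycles | 200 | final polishing per converged member |

## The genetic layer

Every `ga_interval` iterations the maps are gathered and aligned to the
member with the best (lowest-Rwork) fitness. On the aligned
asymmetric-unit chromosomes:

* population statistics Rmin, Ravg, Rthres = Ravg + (Ravg − Rmin);
* pairwise RMS density distances d_ij, convergence scores
  s_i = Σ_j exp(−d²_ij/2σ²) with σ the off-diagonal standard deviation
  (s_i = N when all maps coincide);
* crowding-modified R: Rmod = Rthres − (Rthres − Rwork)/s;
* fitness f = (Rthres − Rmod)/(Rthres − Rmin), clipped at zero; when
  Rthres = Rmin (all Rwork equal) quality cannot discriminate and
  fitness falls back to 1/s, so diversity alone sets the selection
  pressure;
* roulette selection of two independent parents per offspring
  (inverse-CDF sampling, distribution-equivalent to accept–reject);
* crossover, then mutation; offspring are re-expanded to the exactly
  symmetric full cell via orbit representatives and returned to the
  slot's original frame. Elites keep their own density bitwise and stay
  selectable as parents.

**Elite detection** compares the mean Rwork of the past window
(iterations i−300…i−200 at full-scale defaults) with the most recent
window (i−100…i); a drop above 0.02 is convergence, and the flag is
sticky. An Rfree-window check can be required in addition
(`elite_use_rfree`, default on). The desk-scale toy protocol turns the
Rfree gate *off*: with noiseless amplitudes Rfree reaches its floor
(~0.03) during the initial descent, after which a further 0.02 drop is
structurally impossible and the dual gate degenerates into a race
artifact. The gate earns its keep only on noisy data, where Rfree
tracks Rwork.

Termination: all members elite, or max_iter (default 10,000) reached.
Converged members then get the flattening cycles, are aligned to the
best of them and averaged; unconverged members are reported as-is. The
phases of the averaged map are the run's result — averaging converged
maps that approached the solution along different paths cancels their
independent errors (the worked examples show the averaged map beating
typical single members by several degrees of phase error).

## Origin alignment

Allowed transforms are found by brute-force conjugation: shift t (with
optional inversion) is allowed iff conjugating every space-group
operator by it lands in the group modulo lattice translations.
Candidates are enumerated at grid resolution, which handles polar axes
(continuous origin freedom) automatically at the only precision
crossover needs. The alignment objective is protein-mask overlap
(Jaccard index; masks from the σ = 3 Å weighted density at the run's
solvent fraction), evaluated for all shifts at once by FFT
cross-correlation. Transforms are exact index permutations — round
trips are bitwise, and a recovered alignment of a merely-shifted map
restores correlation 1.0 exactly.

## NCS averaging

Known rotational NCS (order, axis direction, axis point) is applied as
real-space averaging over the n rotation images, trilinear
interpolation with periodic wrap; rotations that map grid points onto
grid points (e.g. C4 about a cell axis on a matching grid) are exact.
The staged core masks (σ = 15, 5, 3 Å by default) are a deliberate
simplification of full staged core growth: each stage thresholds the
stage-σ weighted density at the protein quantile, stages 1–2
additionally restricted to a cylinder around the axis (radius σ and 2σ)
so the core grows outward; stage 3 coincides with the ordinary
envelope. Axis determination from the data (self-rotation Patterson
analysis) is out of scope. A quantile envelope cannot respect rotation
orbits when the protein point count is not a multiple of the NCS order;
the split-orbit points dominate max-norm asymmetry measures, which is
why symmetry retention is quantified as relative RMS of the asymmetric
component.

## The synthetic toy crystals

The generator emulates the *inputs* of a phasing experiment without any
external data: Gaussian blobs placed in one contiguous sub-box (a
compact, connected protein), symmetrized over the space group, then
refined by alternating band-limiting with solvent zeroing on a
jointly-updated envelope until envelope and density are
self-consistent. The result is a band-limited truth map whose solvent
is flat to a few tenths of a percent of the unit protein peak — the
irreducible ripple of the over-determined constraint pair — and whose
recomputed envelope equals the stored truth envelope. Amplitude-only
data are taken from the truth (optional multiplicative log-normal
noise), reflections above the beam-stop cutoff (default 15 Å) are
marked unmeasured, and the reference histogram is sampled from the
truth protein region (standing in for the similar-resolution reference
structure a real run would use).

What the toy does **not** emulate: atomicity and B-factors, bulk-solvent
scattering, measurement-error models beyond multiplicative noise,
anisotropy, and data incompleteness patterns beyond the beam-stop gap.
Passing the end-to-end tests therefore demonstrates the machinery —
projection, envelope, histogram, HIO, GA, alignment, averaging —
operating correctly in a solvable regime, not performance on real
diffraction data.

Problem sizes used throughout the tests and the reproduction script: a
20 Å cubic P1 cell at 2 Å resolution (30³ grid, ~2100 unique
reflections, 72% solvent), population 16, genetic operations every 50
iterations, at most 3000 dual-space iterations — a deliberately
desk-scale rendition of the full protocol (100 members, interval 100,
10⁴ iterations). At 72% solvent this toy converges readily; a 45%
solvent variant without NCS is included as a negative control and is
generally not solvable, mirroring the practical ~65% solvent threshold
of the method.

## Numerical choices

* Structure factors are plain DFT sums F(h) = Σ_x g(x) e^{+2πi h·x};
  the hot path runs on the real-FFT half-spectrum (amplitude scaling is
  Friedel-symmetric, so this is exact). All grids are float64.
* Envelope selection uses argpartition with explicit ascending-index
  resolution of threshold ties.
* Histogram matching caches the sorted reference targets per region
  size; ties in the data break by index order, making the transform
  deterministic.
* Symmetrization averages over operator index permutations; the
  asymmetric unit is the set of orbit-minimum grid points, and
  expansion propagates representative values (exact idempotent
  symmetry).
* Crossover segment starts are rejection-resampled until
  non-overlapping on the cyclic index range.
* Per-rank RNG streams are seeded master_seed + rank; the GA uses a
  separate root-only stream; worker pools only ever map pure functions
  over rank states, so serial and multi-process runs are bitwise
  identical.
* Degenerate guards: all-equal weighted density still yields a mask
  (index-order tie-break); all-zero calculated amplitudes raise; an
  empty protein region raises; population fitness falls back to 1/s
  when quality is degenerate.

## Known limitations

* Low solvent content (below ~55–65%) without NCS is out of reach, as
  for the method itself.
* The supported space-group handling requires grid dims compatible with
  every operator (axis-swapping operators need equal dims on the
  swapped axes); incompatible combinations raise rather than resample.
* Minimum-image kernel distances are approximate for strongly oblique
  cells.
* The per-iteration NCS region is the current protein envelope (or a
  staged core mask); full three-stage core *growth* is an extension
  point.
* MPI is not bundled; the worker-pool backend implements the same
  gather–evolve–scatter contract and is the reference implementation of
  it.
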