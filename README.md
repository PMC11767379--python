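# evophase

Genetic-algorithm-enhanced dual-space direct phasing for protein
crystallography.

A diffraction experiment records only structure-factor amplitudes
|F(h)|; the phases φ(h) needed to invert to an electron density map are
lost. When the crystal has a large disordered-solvent region, the
constant density of that region supplies enough constraints to recover
the phases *ab initio* — no homologous model, heavy atoms or predicted
structure required. `evophase` implements the classic dual-space
iteration for this problem and wraps it in a population-level genetic
algorithm that rescues the method from its notorious failure mode:
independent reconstructions stagnating in local minima.

## The method

One dual-space cycle, starting from density g\_k:

1. **Amplitude projection** — FFT to reciprocal space, fit the scale
   λ = Σ|Fobs||Fcal| / Σ|Fcal|² on the working set, record
   Rwork = Σ‖Fobs| − λ|Fcal‖ / Σ|Fobs| (and Rfree on a held-out 1%),
   replace work amplitudes with |Fobs|/λ keeping calculated phases,
   estimate unmeasured amplitudes as
   |Fmiss| = (Σ\_work|Fobs| / Σ\_work|Fcal|)·|Fcal|, and transform back
   to get g′\_k.
2. **Envelope** — compute the Gaussian-weighted local density
   w\_i = Σ\_j exp(−r²\_ij/2σ₀²) g′\_j (σ₀ ramping 4.0 → 3.0 Å) and
   label the top (1 − solvent fraction) of grid points as protein.
3. **Histogram matching** — rank-transform protein-region values onto a
   reference density histogram.
4. **Hybrid input–output (HIO)** — g\_{k+1} = g′\_k (histogram-matched)
   in the protein, g\_k − β·g′\_k in the solvent (β = 0.7): negative
   feedback that drives the solvent toward constancy without hard
   clamping.

The genetic layer runs N such reconstructions in parallel. Every
`ga_interval` iterations the maps are gathered and origin-aligned, and
a new generation is bred:

- fitness f\_i = (Rthres − R\_i)/(Rthres − Rmin) with the adaptive
  threshold Rthres = Ravg + (Ravg − Rmin), zero above Rthres;
- premature-convergence prevention: the RMS density distance d\_ij
  yields a convergence score s\_i = Σ\_j exp(−d²\_ij/2σ²), and crowded
  individuals are penalized through Rmod = Rthres − (Rthres − R)/s;
- roulette-wheel parent selection, 10-segment crossover exchanging 50%
  of asymmetric-unit grid points, 1% uniform-random mutation;
- elites — members whose sliding-window mean Rwork (and Rfree) dropped
  by more than 0.02 — pass to the next generation untouched.

When every member is elite (or the budget is exhausted), converged maps
get 200 cycles of solvent flattening, are aligned and averaged, and the
phases of the average are the result.

## Worked example

No downloads are needed: the package generates toy crystals (Gaussian
blob "proteins" with a genuinely flat bulk solvent, band-limited to the
data resolution, amplitudes only, low-angle data removed by a simulated
beam stop). A single reconstruction from random phases
(`examples/02_single_reconstruction.py`):

```
iteration   500: Rwork 0.277 Rfree 0.048
iteration  1000: Rwork 0.263 Rfree 0.051
iteration  1500: Rwork 0.276 Rfree 0.054
after flattening: Rwork 0.018, map correlation 0.990, mean phase error 38.2 deg
```

During HIO the map hovers near the solution (Rwork is measured *before*
the amplitude reset, so it reflects the churn the solvent feedback
deliberately injects); the final solvent flattening pins it, giving a
map that correlates 0.99 with the ground truth at a 38° mean phase
error — good enough, at this resolution, for model building. A small
population run (`examples/03_evolutionary_run.py`) then shows the point
of averaging:

```
population 8, 300 iterations run
converged (elite) members: 8
mean iterations to convergence: 225
member correlations vs truth: 0.99 0.99 0.99 1.00 0.99 0.98 0.99 0.99
averaged map: Rwork 0.031, correlation 0.994, mean phase error 27.3 deg
```

Each `examples/*.py` script is a short narrative of one capability
(toy-crystal generation, single reconstruction, evolutionary run,
origin alignment, NCS averaging). A thin CLI covers the same ground
from the shell: `evophase synth`, `evophase run config.yaml`,
`evophase score --map recon.ccp4 --truth truth.ccp4`,
`evophase metrics trace.csv`. Real reflection data can be supplied as
MTZ (columns FP/SIGFP, free flag 0 = free) or structure-factor mmCIF
(`_refln.F_meas_au`); maps are written as CCP4/MRC mode 2.

## Scope

Supported space groups include P1, P21212, P212121, P42212 and C121
(any gemmi symbol compatible with the grid is accepted). Rotational
NCS averaging with a *known* axis is built in; determining the axis
from the data (self-rotation Patterson analysis), anomalous scattering,
intensity-to-amplitude conversion and automated model building are out
of scope. See `docs/methods.md` for the model, parameter choices and
limitations.
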