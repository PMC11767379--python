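"""One dual-space reconstruction from random phases, without the GA.

Runs the plain iterative cycle (impose observed amplitudes, separate
protein from solvent, histogram-match the protein, HIO feedback in the
solvent) from a random density, then polishes with solvent flattening,
and scores the result against the known truth.
"""

import dataclasses

import numpy as np

from evophase import (DirectPhaser, PhasingState, ToyCrystalSpec,
                      align_to_reference, density_to_structure_factors,
                      generate_toy_crystal, mean_phase_error,
                      real_space_correlation)
from evophase.grid import DensityGrid
from evophase.reflections import WORK
from evophase.runner import prepare_reflections
from evophase.synthetic import toy_run_config

bundle = generate_toy_crystal(ToyCrystalSpec(seed=3))
cfg = toy_run_config(seed=0)
cfg = dataclasses.replace(
    cfg, phasing=dataclasses.replace(cfg.phasing, max_iter=1500))
refl = prepare_reflections(bundle.reflections, cfg)
phaser = DirectPhaser(refl, bundle.grid_spec, cfg.phasing, bundle.histogram)

rng = np.random.default_rng(0)
state = PhasingState(grid=DensityGrid(bundle.grid_spec,
                                      rng.random(bundle.grid_spec.dims)))
for i in range(1500):
    state = phaser.cycle(state)
    if (i + 1) % 500 == 0:
        print(f"iteration {i+1:5d}: Rwork {state.metrics[-1].rwork:.3f} "
              f"Rfree {state.metrics[-1].rfree:.3f}")

# the converged-run protocol: 200 cycles of solvent flattening
state = PhasingState(grid=state.grid, mode="flatten",
                     iteration=state.iteration, metrics=state.metrics)
for _ in range(200):
    state = phaser.cycle(state)

aligned, transform = align_to_reference(state.grid, bundle.truth,
                                        cfg.phasing.solvent_fraction)
phases = density_to_structure_factors(aligned, refl.hkl)
err = mean_phase_error(bundle.truth_phases.phase, phases.phase,
                       refl.subset(WORK))
print(f"after flattening: Rwork {state.metrics[-1].rwork:.3f}, "
      f"map correlation {real_space_correlation(aligned, bundle.truth):.3f}, "
      f"mean phase error {err:.1f} deg")
# Rwork drops to a few percent and the aligned map correlates > 0.9
# with the truth; a phase error around 40 deg is what a single
# converged reconstruction typically achieves at this resolution.
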