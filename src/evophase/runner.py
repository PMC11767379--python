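"""The full evolutionary phasing run.

A population of reconstructions iterates the dual-space cycle
independently; every ``ga_interval`` iterations the maps are gathered,
origin-aligned to the best-fitness member, evolved (selection /
crossover / mutation with elite preservation and fitness sharing) and
scattered back in their original frames.  When every member is elite
(or the iteration budget is exhausted) each converged map gets a final
block of solvent-flattening cycles; the converged maps are aligned,
averaged, and the phases of the average are the run's result.

Results are deterministic functions of (master seed, config, inputs),
independent of the worker count: per-rank work is a pure function of
the rank state and all random draws use per-rank or root-only streams.
"""

from __future__ import annotations

import concurrent.futures
from dataclasses import dataclass

import numpy as np

from .align import align_to_reference, average_aligned, \
    real_space_correlation, restore_origin
from .config import RunConfig
from .ga import Individual, PopulationState, detect_elite, evolve
from .grid import DensityGrid, PhasedAmplitudes, density_to_structure_factors
from .lattice import GridSpec, SpaceGroupInfo, space_group
from .modify import DirectPhaser, MetricsRecord, PhasingState, ReferenceHistogram, \
    mean_phase_error
from .ncs import NCSAverager
from .reflections import FREE, WORK, ReflectionSet, assign_free_set
from .symmetry import asu_indices, expand_asu, symmetrize_density

__all__ = ["RunResult", "run_single", "run_evolutionary", "prepare_reflections"]


@dataclass
class RunResult:
    """Everything a finished run reports."""

    traces: list[list[MetricsRecord]]
    converged: list[bool]
    elite_iteration: list[int | None]
    members: list[DensityGrid]
    averaged: DensityGrid | None
    phases: PhasedAmplitudes | None
    summary: dict
    successful: bool


def prepare_reflections(refl: ReflectionSet, cfg: RunConfig) -> ReflectionSet:
    """Apply the low-resolution replacement rule and the free-set split."""
    refl = refl.relabel_lowres(cfg.phasing.lowres_cutoff)
    if not np.any(refl.label == FREE):
        refl = assign_free_set(refl, cfg.phasing.free_fraction,
                               seed=cfg.seed + 90_001)
    return refl


def _random_start(spec: GridSpec, sg: SpaceGroupInfo,
                  rng: np.random.Generator) -> DensityGrid:
    g = DensityGrid(spec, rng.random(spec.dims))
    if sg.n_ops > 1:
        g = symmetrize_density(g, sg)
    return g


# -- worker plumbing ---------------------------------------------------------

_WORKER_PHASER: DirectPhaser | None = None


def _init_worker(phaser: DirectPhaser) -> None:
    global _WORKER_PHASER
    _WORKER_PHASER = phaser


def _advance_task(args: tuple[PhasingState, int]) -> PhasingState:
    state, n_cycles = args
    phaser = _WORKER_PHASER
    for _ in range(n_cycles):
        state = phaser.cycle(state)
    return state


class _Pool:
    """Order-preserving map over rank states, serial or multi-process."""

    def __init__(self, phaser: DirectPhaser, workers: int):
        self.phaser = phaser
        self.workers = workers
        self._executor = None
        if workers > 1:
            self._executor = concurrent.futures.ProcessPoolExecutor(
                max_workers=workers, initializer=_init_worker,
                initargs=(phaser,))

    def advance(self, states: list[PhasingState], n: int) -> list[PhasingState]:
        args = [(s, n) for s in states]
        if self._executor is None:
            _init_worker(self.phaser)
            return [_advance_task(a) for a in args]
        return list(self._executor.map(_advance_task, args))

    def close(self) -> None:
        if self._executor is not None:
            self._executor.shutdown()


# -- single-rank run ---------------------------------------------------------

def run_single(cfg: RunConfig, refl: ReflectionSet, spec: GridSpec,
               ref_hist: ReferenceHistogram, sg: SpaceGroupInfo | str = "P1",
               seed: int | None = None) -> tuple[list[MetricsRecord], DensityGrid]:
    """One independent reconstruction without genetic operations.

    Starts from a uniform-random (then symmetrized) density, iterates
    the dual-space cycle until the elite test fires or max_iter is
    reached, then runs the configured solvent-flattening cycles.
    """
    sg = space_group(sg)
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    refl = prepare_reflections(refl, cfg)
    ncs_avg = NCSAverager(cfg.ncs, spec) if cfg.ncs is not None else None
    phaser = DirectPhaser(refl, spec, cfg.phasing, ref_hist, sg,
                          ncs_averager=ncs_avg)
    state = PhasingState(grid=_random_start(spec, sg, rng))
    elite = False
    check_every = max(cfg.ga.ga_interval, 1)
    while state.iteration < cfg.phasing.max_iter:
        state = phaser.cycle(state)
        # elite checks at the same cadence as the population run
        at_check = (state.iteration % check_every == 0
                    or state.iteration == cfg.phasing.max_iter)
        if at_check and _is_elite(state, cfg):
            elite = True
            break
    if elite:
        state = PhasingState(grid=state.grid, iteration=state.iteration,
                             mode="flatten", metrics=state.metrics)
        for _ in range(cfg.phasing.flatten_cycles):
            state = phaser.cycle(state)
    return state.metrics, state.grid


# -- evolutionary run --------------------------------------------------------

def _is_elite(state: PhasingState, cfg: RunConfig) -> bool:
    """Sliding-window drop test on Rwork (and Rfree when configured)."""
    hit = detect_elite(state.rwork_trace, cfg.ga)
    if hit and cfg.ga.elite_use_rfree:
        rfree = state.rfree_trace
        if not np.any(np.isnan(rfree)):
            hit = detect_elite(rfree, cfg.ga)
    return hit


def _update_elites(individuals: list[Individual], states: list[PhasingState],
                   elite_iter: list[int | None], cfg: RunConfig) -> None:
    for ind, state in zip(individuals, states):
        ind.rwork_trace = [m.rwork for m in state.metrics]
        ind.rfree_trace = [m.rfree for m in state.metrics]
        ind.density = state.grid
        if not ind.elite and _is_elite(state, cfg):
            ind.elite = True  # sticky for the rest of the run
            elite_iter[ind.rank_id] = state.iteration


def run_evolutionary(
    cfg: RunConfig,
    refl: ReflectionSet,
    spec: GridSpec,
    ref_hist: ReferenceHistogram,
    sg: SpaceGroupInfo | str = "P1",
    truth: DensityGrid | None = None,
    truth_phases: PhasedAmplitudes | None = None,
) -> RunResult:
    """Run the full population phasing protocol and summarize it.

    If a truth map (and optionally its phases) is supplied, the summary
    additionally reports per-member real-space correlations and the mean
    phase error of the averaged map, both measured after alignment.
    """
    sg = space_group(sg)
    refl = prepare_reflections(refl, cfg)
    ncs_avg = NCSAverager(cfg.ncs, spec) if cfg.ncs is not None else None
    phaser = DirectPhaser(refl, spec, cfg.phasing, ref_hist, sg,
                          ncs_averager=ncs_avg)
    n_pop = cfg.ga.population_size
    asu = asu_indices(sg, spec)
    ga_rng = np.random.default_rng(cfg.seed + 777_001)

    states = []
    for rank in range(n_pop):
        rng = np.random.default_rng(cfg.seed + rank)
        states.append(PhasingState(grid=_random_start(spec, sg, rng)))
    individuals = [Individual(rank_id=r, density=states[r].grid)
                   for r in range(n_pop)]
    elite_iter: list[int | None] = [None] * n_pop

    pool = _Pool(phaser, cfg.workers)
    try:
        iteration = 0
        while iteration < cfg.phasing.max_iter:
            block = min(cfg.ga.ga_interval, cfg.phasing.max_iter - iteration)
            states = pool.advance(states, block)
            iteration += block
            _update_elites(individuals, states, elite_iter, cfg)
            if all(ind.elite for ind in individuals):
                break
            if cfg.ga.enabled and n_pop > 1 and iteration < cfg.phasing.max_iter:
                states = _ga_step(individuals, states, phaser, cfg, ga_rng,
                                  asu, sg)
        converged = [ind.elite for ind in individuals]

        # final solvent flattening on the converged members only;
        # unconverged maps are reported as-is
        flat_idx = [i for i, c in enumerate(converged) if c]
        successful = bool(flat_idx)
        avg_members = flat_idx if successful else list(range(n_pop))
        if flat_idx and cfg.phasing.flatten_cycles > 0 and cfg.phasing.max_iter > 0:
            flat_states = [
                PhasingState(grid=states[i].grid, iteration=states[i].iteration,
                             mode="flatten", metrics=states[i].metrics)
                for i in flat_idx
            ]
            flat_states = pool.advance(flat_states, cfg.phasing.flatten_cycles)
            for i, st in zip(flat_idx, flat_states):
                states[i] = st
    finally:
        pool.close()

    members = [st.grid for st in states]
    traces = [st.metrics for st in states]

    averaged = None
    phases = None
    summary: dict = {
        "population_size": n_pop,
        "success_count": int(sum(converged)),
        "iterations_run": iteration if cfg.phasing.max_iter > 0 else 0,
        "mean_iterations_to_elite": (
            float(np.mean([e for e in elite_iter if e is not None]))
            if any(e is not None for e in elite_iter) else None),
    }
    if cfg.phasing.max_iter > 0 and members:
        # align the averaging set to its lowest-Rwork member and average
        rworks = [t[-1].rwork if t else np.inf for t in traces]
        ref_i = min(avg_members, key=lambda i: rworks[i])
        aligned = []
        for i in avg_members:
            if i == ref_i:
                aligned.append(members[i])
            else:
                a, _ = align_to_reference(members[i], members[ref_i],
                                          cfg.phasing.solvent_fraction, sg)
                aligned.append(a)
        averaged = average_aligned(aligned)
        from .modify import amplitude_projection
        _, scale, rwork_avg, rfree_avg = amplitude_projection(
            averaged, refl, phaser.plan)
        summary["final_rwork"] = rwork_avg
        summary["final_rfree"] = rfree_avg
        phases = density_to_structure_factors(averaged, refl.hkl)

        if truth is not None:
            averaged_t, _ = align_to_reference(
                averaged, truth, cfg.phasing.solvent_fraction, sg)
            summary["averaged_map_correlation"] = real_space_correlation(
                averaged_t, truth)
            corrs = []
            for m in members:
                mt, _ = align_to_reference(m, truth,
                                           cfg.phasing.solvent_fraction, sg)
                corrs.append(real_space_correlation(mt, truth))
            summary["member_correlations"] = corrs
            if truth_phases is not None:
                avg_phases = density_to_structure_factors(averaged_t, refl.hkl)
                work = refl.subset(WORK)
                summary["mean_phase_error_deg"] = mean_phase_error(
                    truth_phases.phase, avg_phases.phase, work)
                phases = avg_phases

    return RunResult(traces=traces, converged=converged,
                     elite_iteration=elite_iter, members=members,
                     averaged=averaged, phases=phases, summary=summary,
                     successful=bool(sum(converged)))


def _ga_step(individuals: list[Individual], states: list[PhasingState],
             phaser: DirectPhaser, cfg: RunConfig,
             ga_rng: np.random.Generator, asu: np.ndarray,
             sg: SpaceGroupInfo) -> list[PhasingState]:
    """Gather, align, evolve, restore frames, scatter."""
    members = [st.grid for st in states]
    rworks = np.array([st.metrics[-1].rwork for st in states])
    ref_i = int(np.argmin(rworks))  # highest raw fitness = lowest Rwork
    aligned = []
    transforms = []
    for i, m in enumerate(members):
        if i == ref_i:
            from .align import FrameTransform
            aligned.append(m)
            transforms.append(FrameTransform((0.0, 0.0, 0.0), False))
        else:
            a, t = align_to_reference(m, members[ref_i],
                                      phaser.cfg.solvent_fraction, sg)
            aligned.append(a)
            transforms.append(t)
    chromosomes = [a.values.ravel()[asu] for a in aligned]
    pop = PopulationState(individuals=individuals)
    offspring = evolve(pop, cfg.ga, ga_rng, chromosomes)

    new_states = []
    for i, (child, st) in enumerate(zip(offspring, states)):
        if child is None:
            new_states.append(st)  # elite: density untouched, own frame
            continue
        full = aligned[i].values.copy().ravel()
        full[asu] = child
        g = DensityGrid(phaser.spec, full.reshape(phaser.spec.dims))
        if sg.n_ops > 1:
            g = expand_asu(g, sg)
        g = restore_origin(g, transforms[i])
        new_states.append(PhasingState(grid=g, iteration=st.iteration,
                                       mode=st.mode, metrics=st.metrics))
    return new_states
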