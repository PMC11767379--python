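"""Population-level evolution of density reconstructions.

A generation holds N independent reconstructions.  Selection pressure
comes from an adaptive fitness built on Rwork with a dynamic threshold
(Rthres = Ravg + (Ravg - Rmin)); premature convergence is prevented by
fitness sharing: a Gaussian-kernel convergence score s_i counts how many
population members are close (in RMS density distance) to individual i,
and inflates its effective R before fitness is computed.  Individuals
whose Rwork dropped sharply (sliding-window test) are elites and are
copied to the next generation unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import GAConfig
from .grid import DensityGrid

__all__ = [
    "Individual",
    "PopulationState",
    "population_stats",
    "fitness",
    "pairwise_density_distance",
    "convergence_scores",
    "modified_r",
    "selection_probabilities",
    "select_parent",
    "detect_elite",
    "crossover",
    "mutate",
    "evolve",
]


@dataclass
class Individual:
    """One reconstruction: its density plus recent R-factor history."""

    rank_id: int
    density: DensityGrid
    rwork_trace: list[float] = field(default_factory=list)
    rfree_trace: list[float] = field(default_factory=list)
    elite: bool = False  # sticky once set


@dataclass
class PopulationState:
    """One GA generation with all derived selection quantities."""

    individuals: list[Individual]
    generation: int = 0
    r_min: float = float("nan")
    r_avg: float = float("nan")
    r_thres: float = float("nan")
    d_matrix: np.ndarray | None = None
    s_scores: np.ndarray | None = None
    r_mod: np.ndarray | None = None
    fitness: np.ndarray | None = None
    select_p: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.individuals)


def population_stats(rwork: np.ndarray) -> tuple[float, float, float]:
    """(Rmin, Ravg, Rthres) with Rthres = Ravg + (Ravg - Rmin)."""
    rwork = np.asarray(rwork, dtype=np.float64)
    if rwork.size == 0:
        raise ValueError("empty population")
    r_min = float(rwork.min())
    r_avg = float(rwork.mean())
    return r_min, r_avg, r_avg + (r_avg - r_min)


def fitness(r_eff: np.ndarray, r_thres: float, r_min: float) -> np.ndarray:
    """Adaptive fitness: linear in (Rthres - R), zero at or above Rthres."""
    r_eff = np.asarray(r_eff, dtype=np.float64)
    if r_thres < r_min:
        raise ValueError("r_thres must be >= r_min")
    span = r_thres - r_min
    if span == 0.0:
        # degenerate population: everyone equally fit
        return np.full(r_eff.shape, 1.0 / max(r_eff.size, 1))
    f = (r_thres - r_eff) / span
    return np.where(r_eff < r_thres, f, 0.0)


def pairwise_density_distance(densities: list[np.ndarray]) -> np.ndarray:
    """RMS deviation between every pair of (flattened) density vectors.

    d_ij = sqrt( (1/N) sum_q (g_q^i - g_q^j)^2 ), computed on the
    asymmetric-unit points of origin-aligned maps.
    """
    mat = np.stack([np.asarray(d, dtype=np.float64).ravel() for d in densities])
    n = mat.shape[1]
    sq = np.sum(mat * mat, axis=1)
    gram = mat @ mat.T
    d2 = (sq[:, None] + sq[None, :] - 2.0 * gram) / n
    d2 = np.maximum(d2, 0.0)
    d = np.sqrt(d2)
    np.fill_diagonal(d, 0.0)
    return 0.5 * (d + d.T)


def convergence_scores(d_matrix: np.ndarray) -> np.ndarray:
    """Gaussian-kernel similarity count s_i = sum_j exp(-d_ij^2 / 2 sigma^2).

    sigma is the standard deviation of the off-diagonal distances; each
    s_i >= 1 because d_ii = 0.  A population of identical maps has
    sigma = 0, in which case s_i = N (the limit of total similarity).
    """
    d = np.asarray(d_matrix, dtype=np.float64)
    n = d.shape[0]
    off = d[~np.eye(n, dtype=bool)]
    sigma = float(off.std()) if off.size else 0.0
    if sigma == 0.0:
        return np.full(n, float(n))
    return np.sum(np.exp(-d * d / (2.0 * sigma * sigma)), axis=1)


def modified_r(rwork: np.ndarray, s: np.ndarray, r_thres: float) -> np.ndarray:
    """Similarity-inflated R: Rmod = Rthres - (Rthres - Rwork) / s.

    Crowded individuals (large s) have their margin below Rthres shrunk,
    lowering their fitness and selection probability.
    """
    rwork = np.asarray(rwork, dtype=np.float64)
    s = np.asarray(s, dtype=np.float64)
    if np.any(s < 1.0 - 1e-12):
        raise ValueError("convergence scores must be >= 1")
    return r_thres - (r_thres - rwork) / s


def selection_probabilities(f: np.ndarray) -> np.ndarray:
    """Roulette-wheel probabilities p_i = f_i / sum f_j."""
    f = np.asarray(f, dtype=np.float64)
    total = f.sum()
    if total <= 0.0:
        # no individual has positive fitness: fall back to uniform
        return np.full(f.shape, 1.0 / f.size)
    return f / total


def select_parent(p: np.ndarray, rng: np.random.Generator) -> int:
    """Draw one parent index by inverse-CDF roulette.

    Distribution-equivalent to accept-reject roulette sampling but with
    a single uniform draw.
    """
    p = np.asarray(p, dtype=np.float64)
    cdf = np.cumsum(p)
    u = rng.random() * cdf[-1]
    return int(np.searchsorted(cdf, u, side="right").clip(0, len(p) - 1))


def detect_elite(trace: np.ndarray, cfg: GAConfig) -> bool:
    """Sliding-window detection of a sudden, sustained drop in R.

    Compares the mean over the past window (iterations i-300 .. i-200
    with the default window lengths) against the mean over the most
    recent window (i-100 .. i); a drop above elite_drop_threshold marks
    the reconstruction as converged (elite).
    """
    trace = np.asarray(trace, dtype=np.float64)
    need = cfg.window_recent + cfg.window_gap + cfg.window_past + 1
    if trace.size < need:
        return False
    recent = trace[-cfg.window_recent:]
    past_end = trace.size - cfg.window_recent - cfg.window_gap
    past = trace[past_end - cfg.window_past: past_end]
    drop = float(past.mean() - recent.mean())
    return drop > cfg.elite_drop_threshold


def _segment_starts(n_points: int, seg_len: int, n_segments: int,
                    rng: np.random.Generator) -> np.ndarray:
    """Uniform-random non-overlapping segment start positions.

    Starts are drawn by rejection resampling on the cyclic index range
    [0, n_points); segments must not overlap (wrap-around included).
    """
    for _ in range(10_000):
        starts = np.sort(rng.integers(0, n_points, size=n_segments))
        gaps_ok = True
        for i in range(n_segments):
            nxt = starts[(i + 1) % n_segments]
            gap = (nxt - starts[i]) % n_points
            if n_segments > 1 and gap < seg_len:
                gaps_ok = False
                break
        if gaps_ok:
            return starts
    raise RuntimeError("could not place non-overlapping crossover segments")


def crossover(a: np.ndarray, b: np.ndarray, cfg: GAConfig,
              rng: np.random.Generator) -> np.ndarray:
    """Multi-segment crossover on flattened chromosome vectors.

    The offspring is a copy of parent ``a`` with ``n_segments``
    disjoint contiguous index runs replaced by parent ``b``'s values;
    the total replaced length is round(crossover_fraction * N) split as
    evenly as possible across the segments.
    """
    a = np.asarray(a, dtype=np.float64).ravel()
    b = np.asarray(b, dtype=np.float64).ravel()
    if a.shape != b.shape:
        raise ValueError("parents must have equal length")
    n = a.size
    total = int(round(cfg.crossover_fraction * n))
    if total < cfg.n_segments:
        raise ValueError("crossover_fraction * N smaller than n_segments")
    base, extra = divmod(total, cfg.n_segments)
    seg_lens = np.full(cfg.n_segments, base, dtype=np.int64)
    seg_lens[:extra] += 1
    starts = _segment_starts(n, int(seg_lens.max()), cfg.n_segments, rng)
    child = a.copy()
    for start, length in zip(starts, seg_lens):
        idx = (start + np.arange(length)) % n
        child[idx] = b[idx]
    return child


def mutate(g: np.ndarray, cfg: GAConfig, rng: np.random.Generator) -> np.ndarray:
    """Replace floor(mutation_rate * N) distinct points by uniform draws.

    New values are uniform on the open interval given by mutation_range
    (default (0, 1), the normalized density scale); all other points are
    copied bit-for-bit.
    """
    g = np.asarray(g, dtype=np.float64).ravel()
    n = g.size
    k = int(np.floor(cfg.mutation_rate * n))
    out = g.copy()
    if k == 0:
        return out
    sites = rng.choice(n, size=k, replace=False)
    lo, hi = cfg.mutation_range
    out[sites] = lo + (hi - lo) * rng.random(k)
    return out


def evaluate_population(pop: PopulationState, cfg: GAConfig,
                        chromosomes: list[np.ndarray]) -> PopulationState:
    """Fill in the derived selection quantities for the generation.

    ``chromosomes`` are the origin-aligned asymmetric-unit vectors used
    for the diversity distances; Rwork values come from the tail of each
    individual's trace.
    """
    rwork = np.array([ind.rwork_trace[-1] for ind in pop.individuals])
    r_min, r_avg, r_thres = population_stats(rwork)
    d = pairwise_density_distance(chromosomes)
    s = convergence_scores(d)
    r_mod = modified_r(rwork, s, r_thres)
    if r_thres > r_min:
        f = fitness(r_mod, r_thres, r_min)
    else:
        # all Rwork equal: amplitude quality cannot discriminate, so
        # selection pressure falls back to diversity alone
        f = 1.0 / s
    p = selection_probabilities(f)
    pop.r_min, pop.r_avg, pop.r_thres = r_min, r_avg, r_thres
    pop.d_matrix, pop.s_scores, pop.r_mod = d, s, r_mod
    pop.fitness, pop.select_p = f, p
    return pop


def evolve(pop: PopulationState, cfg: GAConfig, rng: np.random.Generator,
           chromosomes: list[np.ndarray]) -> list[np.ndarray | None]:
    """One generation of selection, crossover and mutation.

    Operates on origin-aligned chromosome vectors.  Returns one entry
    per slot: ``None`` for elites (their density is inherited unchanged,
    in their own original frame) and the offspring chromosome otherwise.
    Both parents of an offspring are drawn independently by roulette
    over the similarity-modified fitness; elites remain selectable as
    parents.
    """
    pop = evaluate_population(pop, cfg, chromosomes)
    out: list[np.ndarray | None] = []
    for ind in pop.individuals:
        if ind.elite:
            out.append(None)
            continue
        pa = select_parent(pop.select_p, rng)
        pb = select_parent(pop.select_p, rng)
        child = crossover(chromosomes[pa], chromosomes[pb], cfg, rng)
        child = mutate(child, cfg, rng)
        out.append(child)
    pop.generation += 1
    return out
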