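"""Run configuration: every tunable of the phasing cycle and the GA.

All defaults are the published operating point of the method where one
exists (feedback strength, sigma schedule endpoints, GA rates, elite
windows); the remaining knobs are standard crystallographic practice and
are documented in the methods note.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["PhasingConfig", "GAConfig", "NCSConfig", "RunConfig"]


@dataclass
class PhasingConfig:
    """Parameters of one dual-space density-modification cycle."""

    solvent_fraction: float = 0.70  # user's estimate; underestimate on purpose
    beta: float = 0.7               # HIO negative-feedback strength, (0, 1]
    sigma_start: float = 4.0        # Gaussian averaging radius at iteration 0 (A)
    sigma_end: float = 3.0          # radius after the ramp (A)
    sigma_ramp_fraction: float = 0.6  # fraction of max_iter over which sigma ramps
    lowres_cutoff: float = 15.0     # replace measured data beyond this d (A)
    free_fraction: float = 0.01
    max_iter: int = 10_000
    flatten_cycles: int = 200       # solvent-flattening cycles after convergence
    flatten_histogram_match: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.solvent_fraction < 1.0:
            raise ValueError("solvent_fraction must lie in (0, 1)")
        if not 0.0 < self.beta <= 1.0:
            raise ValueError("beta must lie in (0, 1]")
        if self.sigma_end > self.sigma_start:
            raise ValueError("sigma_end must not exceed sigma_start")
        if self.max_iter < 0:
            raise ValueError("max_iter must be nonnegative")


@dataclass
class GAConfig:
    """Genetic-engine parameters (population-level evolution)."""

    population_size: int = 100
    ga_interval: int = 100          # dual-space iterations between GA steps
    crossover_fraction: float = 0.50
    n_segments: int = 10
    mutation_rate: float = 0.01
    mutation_range: tuple[float, float] = (0.0, 1.0)
    elite_drop_threshold: float = 0.02
    window_recent: int = 100        # recent R-factor window length
    window_past: int = 100          # past window length
    window_gap: int = 100           # gap between the two windows
    elite_use_rfree: bool = True    # require the Rfree windows to drop as well
    enabled: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.crossover_fraction < 1.0:
            raise ValueError("crossover_fraction must lie in (0, 1)")
        if self.n_segments < 1:
            raise ValueError("n_segments must be >= 1")
        if not 0.0 <= self.mutation_rate < 1.0:
            raise ValueError("mutation_rate must lie in [0, 1)")


@dataclass
class NCSConfig:
    """Known rotational non-crystallographic symmetry, if any."""

    order: int = 2
    axis_direction: tuple[float, float, float] = (0.0, 0.0, 1.0)
    axis_point: tuple[float, float, float] = (0.0, 0.0, 0.0)  # fractional
    core_sigmas: tuple[float, float, float] = (15.0, 5.0, 3.0)

    def __post_init__(self) -> None:
        if self.order < 2:
            raise ValueError("NCS order must be >= 2")
        if all(abs(x) < 1e-12 for x in self.axis_direction):
            raise ValueError("NCS axis direction must be nonzero")
        r1, r2, r3 = self.core_sigmas
        if not (r1 > 0 and r2 > 0 and r3 > 0 and r1 >= r2 >= r3):
            raise ValueError("core_sigmas must be positive and non-increasing")


@dataclass
class RunConfig:
    """Everything a full evolutionary phasing run needs."""

    phasing: PhasingConfig = field(default_factory=PhasingConfig)
    ga: GAConfig = field(default_factory=GAConfig)
    ncs: NCSConfig | None = None
    seed: int = 0
    workers: int = 1
    reflections_path: str | None = None
    histogram_path: str | None = None
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.phasing.max_iter and self.ga.enabled and \
                self.phasing.max_iter < self.ga.ga_interval:
            raise ValueError("max_iter must be >= ga_interval")
        if self.workers < 1:
            raise ValueError("workers must be >= 1")

    # -- YAML round trip ------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "phasing" in d and isinstance(d["phasing"], dict):
            d["phasing"] = PhasingConfig(**d["phasing"])
        if "ga" in d and isinstance(d["ga"], dict):
            ga = dict(d["ga"])
            if "mutation_range" in ga:
                ga["mutation_range"] = tuple(ga["mutation_range"])
            d["ga"] = GAConfig(**ga)
        if d.get("ncs") is not None and isinstance(d["ncs"], dict):
            ncs = dict(d["ncs"])
            for key in ("axis_direction", "axis_point", "core_sigmas"):
                if key in ncs:
                    ncs[key] = tuple(ncs[key])
            d["ncs"] = NCSConfig(**ncs)
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_plainify(self.to_dict()), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _plainify(obj):
    """Recursively turn tuples into lists so YAML stays plain."""
    if isinstance(obj, dict):
        return {k: _plainify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plainify(v) for v in obj]
    return obj
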