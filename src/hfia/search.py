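"""Stage-2 wrapper: an improved clonal-selection search over feature masks.

Candidate subsets are *antibodies* — binary vectors over the filtered
feature space — evolved by the classic clonal-selection loop (evaluate,
select the elite, clone in proportion to rank, hypermutate, update the
population) with four modifications aimed at high-dimensional feature
selection:

* **Cauchy initialization** — gene activations come from thresholding
  standard-Cauchy draws at ``eta`` (default -0.2), giving dense but
  heavy-tailed starting subsets.
* **Conditional lethal mutation** — while the best fitness keeps
  improving, mutation only *deactivates* genes (threshold ``delta``
  shrinking linearly from 0.5 to -0.5 recruits ever more loci), driving
  the search toward smaller subsets; on stagnation it reverts to ordinary
  bit-flips to restore exploration.
* **Incremental update** — every generation injects N fresh Cauchy
  antibodies whose activation threshold ``eta + theta`` rises linearly,
  so newcomers grow progressively sparser.
* **Elitist merge-and-truncate** — parents, mutated clones and newcomers
  compete; the N best survive, so the best fitness never worsens.

The loop minimises the evaluator fitness (affinity = -fitness, so the
"highest-affinity" elite is the lowest-fitness prefix).  All randomness
derives from one master seed through numpy SeedSequence spawning, making
runs bit-reproducible.
"""

from __future__ import annotations

import copy
import logging
import math
from dataclasses import dataclass, field, replace, asdict
from typing import Callable, Sequence

import numpy as np

from .data_io import LabeledDataset, SelectionResult
from .evaluation import FitnessCache, FitnessConfig, evaluate_mask
from .fisher import FilteredDataset, fisher_scores, select_top_k

__all__ = [
    "Antibody",
    "HFIAConfig",
    "ScheduleState",
    "Population",
    "sample_standard_cauchy",
    "cauchy_cdf",
    "init_population",
    "schedule",
    "select_elites",
    "clone",
    "lethal_mutation",
    "population_update",
    "optimize",
    "run_hfia",
]

logger = logging.getLogger("hfia")


# ---------------------------------------------------------------------------
# Cauchy machinery

def sample_standard_cauchy(count: int, rng: np.random.Generator) -> np.ndarray:
    """I.i.d. draws from the standard Cauchy distribution (x0=0, gamma=1)."""
    return rng.standard_cauchy(count)


def cauchy_cdf(x, x0: float = 0.0, gamma: float = 1.0):
    """Cauchy cumulative distribution: arctan((x - x0)/gamma)/pi + 0.5."""
    if gamma <= 0:
        raise ValueError(f"gamma must be positive, got {gamma}")
    return np.arctan((np.asarray(x, dtype=float) - x0) / gamma) / np.pi + 0.5


# ---------------------------------------------------------------------------
# Domain types

@dataclass
class Antibody:
    """A candidate subset: bit j set means filtered feature j is selected."""

    code: np.ndarray
    fitness: float | None = None

    def __post_init__(self) -> None:
        self.code = np.asarray(self.code, dtype=bool)

    @property
    def n_active(self) -> int:
        return int(self.code.sum())

    def copy(self) -> "Antibody":
        return Antibody(code=self.code.copy(), fitness=self.fitness)


@dataclass(frozen=True)
class HFIAConfig:
    """Search parameters.

    Defaults are the standard operating point: 50 iterations over a
    population of 10 with select rate 0.5 (elite pool of 5), Cauchy
    activation threshold -0.2 and clone factor 1.
    """

    N: int = 10
    c_r: float = 0.5
    Tmax: int = 50
    eta: float = -0.2
    beta: float = 1.0
    fisher_k: int = 200
    fitness_config: FitnessConfig = field(default_factory=FitnessConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError(f"population size N must be >= 2, got {self.N}")
        if not 0.0 < self.c_r <= 1.0:
            raise ValueError(f"select rate c_r must be in (0, 1], got {self.c_r}")
        if self.Tmax < 0:
            raise ValueError(f"Tmax must be >= 0, got {self.Tmax}")
        if self.beta <= 0:
            raise ValueError(f"clone factor beta must be > 0, got {self.beta}")
        if self.selection_pool_size < 1:
            raise ValueError("selection pool size round(c_r * N) must be >= 1")

    @property
    def selection_pool_size(self) -> int:
        return round(self.c_r * self.N)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["fitness_config"] = asdict(self.fitness_config)
        return d


@dataclass(frozen=True)
class ScheduleState:
    """Iteration counter with the two linear adaptive factors.

    ``delta = 0.5 - t/Tmax`` is the mutation-locus threshold (falls from
    0.5 toward -0.5, recruiting more loci); ``theta = t/Tmax`` raises the
    activation threshold of fresh antibodies (they grow sparser);
    ``best_improved`` records whether the best fitness strictly improved
    at the previous iteration and gates the lethal mutation mode.
    """

    t: int
    Tmax: int
    best_improved: bool = True

    def __post_init__(self) -> None:
        if self.Tmax < 1:
            raise ValueError("Tmax must be >= 1")
        if not 0 <= self.t <= self.Tmax:
            raise ValueError(f"t must lie in [0, Tmax], got t={self.t}")

    @property
    def delta(self) -> float:
        return 0.5 - self.t / self.Tmax

    @property
    def theta(self) -> float:
        return self.t / self.Tmax


def schedule(t: int, Tmax: int, best_improved: bool = True) -> ScheduleState:
    """Adaptive factors at iteration ``t`` of ``Tmax``."""
    return ScheduleState(t=t, Tmax=Tmax, best_improved=best_improved)


@dataclass
class Population:
    members: list[Antibody]
    generation: int = 0

    @property
    def best(self) -> Antibody:
        return min(self.members, key=lambda ab: ab.fitness)


# ---------------------------------------------------------------------------
# Operators

def _threshold_antibodies(n: int, m: int, threshold: float,
                          rng: np.random.Generator) -> list[Antibody]:
    """n antibodies whose genes activate iff a standard-Cauchy draw > threshold.

    All-zero codes are repaired by activating one uniformly random locus,
    keeping every subset non-empty.
    """
    draws = rng.standard_cauchy((n, m))
    codes = draws > threshold
    out = []
    for row in codes:
        if not row.any():
            row[rng.integers(m)] = True
        out.append(Antibody(code=row))
    return out


def init_population(m: int, config: HFIAConfig,
                    rng: np.random.Generator) -> Population:
    """Cauchy-threshold initialization: N antibodies over m genes."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return Population(members=_threshold_antibodies(config.N, m, config.eta, rng))


def select_elites(population: Population, config: HFIAConfig) -> list[Antibody]:
    """The round(c_r * N) lowest-fitness members, ascending.

    Ties break by fewer active genes, then by insertion order.
    """
    order = sorted(range(len(population.members)),
                   key=lambda i: (population.members[i].fitness,
                                  population.members[i].n_active, i))
    n = config.selection_pool_size
    return [population.members[i] for i in order[:n]]


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def clone(elite: Sequence[Antibody], config: HFIAConfig) -> list[Antibody]:
    """Rank-proportional cloning: rank i contributes round(beta*N/i) copies.

    Copies are independent deep copies; mutating one never alters another.
    """
    if not elite:
        raise ValueError("selection set is empty")
    clones: list[Antibody] = []
    for rank, ab in enumerate(elite, start=1):
        count = max(1, _round_half_away(config.beta * config.N / rank))
        clones.extend(ab.copy() for _ in range(count))
    return clones


def lethal_mutation(clones: Sequence[Antibody], state: ScheduleState,
                    rng: np.random.Generator) -> list[Antibody]:
    """Cauchy-driven hypermutation of the clone set (in place).

    Each locus receives a standard-Cauchy draw; loci whose draw exceeds
    ``state.delta`` mutate — a smaller delta recruits more loci.  In
    lethal mode (the best fitness improved last iteration) mutation only
    deactivates: active mutation loci switch off, so the gene count never
    grows.  Otherwise mutation loci bit-flip.  Emptied antibodies are
    repaired to one random active gene; cached fitness is invalidated.
    """
    for ab in clones:
        loci = rng.standard_cauchy(ab.code.shape[0]) > state.delta
        if state.best_improved:
            ab.code[loci] = False  # deactivation only
        else:
            ab.code[loci] = ~ab.code[loci]
        if not ab.code.any():
            ab.code[rng.integers(ab.code.shape[0])] = True
        ab.fitness = None
    return list(clones)


def population_update(population: Population, mutated: Sequence[Antibody],
                      state: ScheduleState, config: HFIAConfig,
                      eval_fn: Callable[[np.ndarray], float],
                      rng: np.random.Generator) -> Population:
    """Incremental elitist update: inject N fresh antibodies, keep the N best.

    Fresh antibodies use activation threshold ``eta + theta``, so they are
    progressively sparser as the run advances.  Parents, mutated clones
    and newcomers compete; survivors are the N lowest-fitness antibodies
    (ties: fewer genes, then earlier origin in the order parents, mutated,
    fresh).  The previous best is in the pool, so the best fitness is
    non-increasing.
    """
    m = population.members[0].code.shape[0]
    fresh = _threshold_antibodies(config.N, m, config.eta + state.theta, rng)
    pool = list(population.members) + list(mutated) + fresh
    for ab in pool:
        if ab.fitness is None:
            ab.fitness = eval_fn(ab.code)
    order = sorted(range(len(pool)),
                   key=lambda i: (pool[i].fitness, pool[i].n_active, i))
    survivors = [pool[i] for i in order[:config.N]]
    return Population(members=survivors, generation=population.generation + 1)


# ---------------------------------------------------------------------------
# Main loop

def optimize(m: int, eval_fn: Callable[[np.ndarray], float],
             config: HFIAConfig, rng: np.random.Generator
             ) -> tuple[Antibody, list[float]]:
    """Run the clonal-selection loop over an m-bit mask space.

    ``eval_fn`` maps a boolean mask to the fitness to minimise.  Returns
    the best antibody and the (Tmax+1)-long non-increasing trajectory of
    the best fitness (after initialization, then after each iteration).
    """
    population = init_population(m, config, rng)
    for ab in population.members:
        ab.fitness = eval_fn(ab.code)
    best = population.best.copy()
    trajectory = [best.fitness]
    best_improved = True  # lethal mode engaged at t=1

    for t in range(1, config.Tmax + 1):
        state = schedule(t, config.Tmax, best_improved)
        elite = select_elites(population, config)
        clones = clone(elite, config)
        mutated = lethal_mutation(clones, state, rng)
        population = population_update(population, mutated, state, config,
                                       eval_fn, rng)
        new_best = population.best
        best_improved = new_best.fitness < best.fitness
        if best_improved:
            best = new_best.copy()
        trajectory.append(best.fitness)
        logger.debug("iter %d/%d: best fitness %.6f, %d genes",
                     t, config.Tmax, best.fitness, best.n_active)
    return best, trajectory


def run_hfia(dataset: LabeledDataset, config: HFIAConfig | None = None
             ) -> SelectionResult:
    """Two-stage hybrid feature selection on a labelled dataset.

    Stage 1 ranks all features by Fisher score and keeps the top
    ``min(fisher_k, q)`` candidates; stage 2 runs the clonal-selection
    search over that candidate space with the KNN-CV fitness.  The best
    antibody's active loci are mapped back to original feature indices.
    A fixed seed yields a bit-identical result; the reported final error
    rate re-evaluates the selected subset on freshly seeded folds.
    """
    if config is None:
        config = HFIAConfig()

    master = np.random.SeedSequence(config.seed)
    search_ss, fold_ss, final_ss = master.spawn(3)
    rng = np.random.default_rng(search_ss)
    fold_seed = int(fold_ss.generate_state(1)[0] % (2**31 - 1))
    final_seed = int(final_ss.generate_state(1)[0] % (2**31 - 1))
    fit_cfg = replace(config.fitness_config, seed=fold_seed)

    scores = fisher_scores(dataset)
    filtered = select_top_k(scores, dataset, config.fisher_k)
    logger.info("Fisher filter: %d of %d features retained",
                filtered.m, dataset.n_features)

    cache = FitnessCache()
    fds = filtered.dataset

    def eval_fn(mask: np.ndarray) -> float:
        return evaluate_mask(mask, fds, fit_cfg, cache).fitness

    if config.Tmax == 0:
        population = init_population(filtered.m, config, rng)
        for ab in population.members:
            ab.fitness = eval_fn(ab.code)
        best, trajectory = population.best.copy(), [population.best.fitness]
    else:
        best, trajectory = optimize(filtered.m, eval_fn, config, rng)

    selected = np.sort(filtered.original_indices[best.code])
    final_cfg = replace(fit_cfg, seed=final_seed)
    final_err = evaluate_mask(best.code, fds, final_cfg).error_rate
    logger.info("selected %d/%d features, final CV accuracy %.4f "
                "(%d classifier evaluations)", len(selected),
                dataset.n_features, 1.0 - final_err, cache.n_evaluations + 1)

    return SelectionResult(
        selected_features=tuple(int(i) for i in selected),
        selected_feature_names=tuple(dataset.feature_names[i] for i in selected),
        best_fitness_trajectory=tuple(trajectory),
        final_error_rate=float(final_err),
        final_accuracy=float(1.0 - final_err),
        n_total_features=dataset.n_features,
        config_echo=config.to_dict(),
        seed=config.seed,
    )
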