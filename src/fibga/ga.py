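"""Real-coded genetic algorithm with rank-based selection, and its
fault-injection fitness variant.

One generation of the canonical configuration holds 20 individuals and is
rebuilt as: the 2 elites (lowest error, copied unchanged), 14 crossover
children and 4 mutation children.  Parents come from a single stochastic
universal sampling (SUS) pass that draws 2*14 + 4 = 32 parents at once from
rank-scaled probabilities P_i = (1/sqrt(Rank_i)) / Σ_j 1/sqrt(j).

Two fitness functions are provided:

* plain fitness (GE): the fault-free mean absolute error, eq. ``(1/N) Σ |c_p − y_p|``;
* fault-injection fitness (FIB): the mean of that error over all 4H+1
  single-parameter stuck-at-zero variants of the genome.  The fault-free
  network itself is *not* part of the average.

Training minimizes fitness; "best" always means lowest error.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, List, Optional, Sequence

import numpy as np

from .network import FeedforwardNet, NetworkConfig, forward_batch
from .problems import Dataset

__all__ = [
    "GAConfig",
    "Individual",
    "TrainResult",
    "GEFitness",
    "FIBFitness",
    "ge_fitness",
    "fib_fitness",
    "rank_population",
    "selection_probabilities",
    "sus_select",
    "crossover",
    "mutation_sigma",
    "mutate",
    "evolve_generation",
    "train_ga",
]


@dataclass(frozen=True)
class GAConfig:
    """GA hyper-parameters; defaults are the canonical study conditions."""

    pop_size: int = 20
    n_elite: int = 2
    n_crossover: int = 14
    n_mutation: int = 4
    max_generations: int = 1000
    error_tolerance: float = 0.001
    sigma_initial: float = 1.0
    #: What the termination test measures for the best-by-fitness individual:
    #: "eq1" (fault-free mean absolute error, the same condition every
    #: trainer is judged by) or "fitness" (the selection objective).
    stop_on: str = "eq1"
    init_bounds: tuple = (-1.0, 1.0)

    def __post_init__(self):
        if self.n_elite + self.n_crossover + self.n_mutation != self.pop_size:
            raise ValueError("n_elite + n_crossover + n_mutation must equal pop_size")
        if self.stop_on not in ("eq1", "fitness"):
            raise ValueError("stop_on must be 'eq1' or 'fitness'")

    @property
    def n_parents(self) -> int:
        return 2 * self.n_crossover + self.n_mutation


@dataclass
class Individual:
    """One genome with its evaluated fitness and (1-based) rank."""

    genome: np.ndarray
    fitness: Optional[float] = None
    rank: Optional[int] = None


@dataclass
class TrainResult:
    """Outcome of one training run (shared by the GA and gradient trainers).

    ``best_error_trace`` records the minimized objective per generation/epoch
    (monotone non-increasing for the GA thanks to elitism).  ``final_error``
    is always the fault-free mean absolute error of ``best_net``, whatever
    the objective was.
    """

    best_net: FeedforwardNet
    best_error_trace: np.ndarray
    terminated_at: int
    termination_reason: str  # "tolerance" | "max_iterations" | "diverged"
    final_error: float
    seed: Optional[int] = None

    def __post_init__(self):
        self.best_error_trace = np.asarray(self.best_error_trace, dtype=float)
        if len(self.best_error_trace) != self.terminated_at:
            raise ValueError("trace length must equal terminated_at")


# -- fitness ------------------------------------------------------------------


class GEFitness:
    """Fault-free mean absolute error of a genome on a dataset."""

    def __init__(self, dataset: Dataset, net_config: NetworkConfig):
        self.dataset = dataset
        self.net_config = net_config

    def batch(self, genomes: np.ndarray) -> np.ndarray:
        outputs = forward_batch(genomes, self.dataset.inputs, self.net_config.n_hidden)
        return np.mean(np.abs(outputs - self.dataset.targets), axis=1)

    def __call__(self, genome: np.ndarray) -> float:
        return float(self.batch(np.asarray(genome, dtype=float)[None, :])[0])


class FIBFitness:
    """Fault-injection fitness: mean error over all single stuck-at-zero faults.

    For a genome of P = 4H+1 parameters this evaluates P variants, the i-th
    having only parameter i forced to 0, and averages their fault-free-style
    errors; the unfaulted genome is excluded from the average.
    """

    def __init__(self, dataset: Dataset, net_config: NetworkConfig):
        self.dataset = dataset
        self.net_config = net_config

    def batch(self, genomes: np.ndarray) -> np.ndarray:
        genomes = np.asarray(genomes, dtype=float)
        B, P = genomes.shape
        if P != self.net_config.n_params:
            raise ValueError("genome length does not match network config")
        # (B, P, P): for each genome, P copies with one parameter zeroed
        faulted = np.repeat(genomes[:, None, :], P, axis=1)
        diag = np.arange(P)
        faulted[:, diag, diag] = 0.0
        outputs = forward_batch(
            faulted.reshape(B * P, P), self.dataset.inputs, self.net_config.n_hidden
        )
        errors = np.mean(np.abs(outputs - self.dataset.targets), axis=1)
        return errors.reshape(B, P).mean(axis=1)

    def __call__(self, genome: np.ndarray) -> float:
        return float(self.batch(np.asarray(genome, dtype=float)[None, :])[0])


def ge_fitness(genome: np.ndarray, dataset: Dataset, config: NetworkConfig) -> float:
    """Functional form of :class:`GEFitness`."""
    return GEFitness(dataset, config)(genome)


def fib_fitness(genome: np.ndarray, dataset: Dataset, config: NetworkConfig) -> float:
    """Functional form of :class:`FIBFitness`."""
    return FIBFitness(dataset, config)(genome)


# -- selection ----------------------------------------------------------------


def rank_population(pop: List[Individual]) -> List[Individual]:
    """Assign ranks 1..n by ascending fitness; ties keep population order.

    The stable tie-break guarantees distinct ranks, which the rank-scaled
    selection probabilities require.
    """
    for ind in pop:
        if ind.fitness is None:
            raise ValueError("all individuals must be evaluated before ranking")
    order = np.argsort([ind.fitness for ind in pop], kind="stable")
    for rank0, idx in enumerate(order):
        pop[idx].rank = rank0 + 1
    return pop


def selection_probabilities(ranks: Sequence[int], pop_size: int) -> np.ndarray:
    """P_i = (1/sqrt(Rank_i)) / Σ_{j=1..pop_size} 1/sqrt(j).

    For pop_size 20 the normalizer is 7.5953 (to 4 decimals).  Probabilities
    sum to 1 and decrease strictly with rank.
    """
    ranks = np.asarray(ranks, dtype=int)
    if sorted(ranks.tolist()) != list(range(1, pop_size + 1)):
        raise ValueError("ranks must be a permutation of 1..pop_size")
    denom = np.sum(1.0 / np.sqrt(np.arange(1, pop_size + 1)))
    return (1.0 / np.sqrt(ranks)) / denom


def sus_select(
    probabilities: np.ndarray, n_parents: int, rng: np.random.Generator
) -> np.ndarray:
    """Stochastic universal sampling: one spin, equally spaced cursors.

    Lays the probabilities end to end on [0, 1), draws a single offset
    uniform on (0, 1/n_parents) and reads off the individuals under cursors
    offset + k/n_parents.  Low-variance: individual i appears either
    floor(n·P_i) or ceil(n·P_i) times.  Returns indices (repeats allowed).
    """
    probabilities = np.asarray(probabilities, dtype=float)
    if n_parents < 1:
        raise ValueError("n_parents must be >= 1")
    if not np.isclose(probabilities.sum(), 1.0):
        raise ValueError("probabilities must sum to 1")
    step = 1.0 / n_parents
    offset = rng.uniform(0.0, step)
    cursors = offset + step * np.arange(n_parents)
    edges = np.cumsum(probabilities)
    edges[-1] = 1.0  # guard against rounding at the top end
    return np.searchsorted(edges, cursors, side="right").astype(int)


# -- variation ----------------------------------------------------------------


def crossover(
    parent1: np.ndarray, parent2: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Uniform crossover: each coordinate taken from parent1 or parent2.

    The binary mask comes from rounding uniform (0,1) draws, so each bit is
    1 with probability 1/2; mask 1 selects parent1.
    """
    parent1 = np.asarray(parent1, dtype=float)
    parent2 = np.asarray(parent2, dtype=float)
    if parent1.shape != parent2.shape:
        raise ValueError("parents must have equal length")
    mask = np.rint(rng.uniform(0.0, 1.0, size=parent1.shape))
    return parent1 * mask + parent2 * np.abs(mask - 1.0)


def mutation_sigma(generation: int, max_generations: int, sigma_initial: float = 1.0) -> float:
    """Linearly shrinking mutation scale: sigma_initial at generation 1, 0 at the cap."""
    if not 1 <= generation <= max_generations:
        raise ValueError("generation out of range")
    if max_generations == 1:
        return 0.0
    return sigma_initial * (1.0 - (generation - 1) / (max_generations - 1))


def mutate(parent: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Add i.i.d. Gaussian(0, sigma) noise to every coordinate (no clipping)."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    parent = np.asarray(parent, dtype=float)
    if sigma == 0:
        return parent.copy()
    return parent + rng.normal(0.0, sigma, size=parent.shape)


# -- generational loop --------------------------------------------------------


def _evaluate_batch(fitness_fn, genomes: np.ndarray) -> np.ndarray:
    if hasattr(fitness_fn, "batch"):
        return np.asarray(fitness_fn.batch(genomes), dtype=float)
    return np.array([float(fitness_fn(g)) for g in genomes])


def evolve_generation(
    pop: List[Individual],
    fitness_fn: Callable,
    generation: int,
    config: GAConfig,
    rng: np.random.Generator,
) -> List[Individual]:
    """Build the next population from a ranked, evaluated one.

    Elites are the ``n_elite`` lowest-error individuals, copied unchanged.
    The SUS parent list is randomly permuted, then consumed in order:
    positions 0..2*n_crossover-1 pair consecutively for crossover; the last
    n_mutation positions feed mutation with the generation's shrinking
    sigma.  The permutation matters: SUS emits cursor-ordered parents, so
    copies of the same individual sit adjacent and consecutive pairing
    would cross individuals with themselves, stalling the search.
    """
    if any(ind.rank is None for ind in pop):
        raise ValueError("population must be ranked")
    by_rank = sorted(pop, key=lambda ind: ind.rank)
    elites = [
        Individual(genome=ind.genome.copy(), fitness=ind.fitness)
        for ind in by_rank[: config.n_elite]
    ]

    probs = selection_probabilities([ind.rank for ind in pop], config.pop_size)
    parents = rng.permutation(sus_select(probs, config.n_parents, rng))

    children = []
    for k in range(config.n_crossover):
        p1 = pop[parents[2 * k]].genome
        p2 = pop[parents[2 * k + 1]].genome
        children.append(crossover(p1, p2, rng))
    sigma = mutation_sigma(generation, config.max_generations, config.sigma_initial)
    for k in range(config.n_mutation):
        p = pop[parents[2 * config.n_crossover + k]].genome
        children.append(mutate(p, sigma, rng))

    child_fitness = _evaluate_batch(fitness_fn, np.asarray(children))
    new_pop = elites + [
        Individual(genome=g, fitness=float(f)) for g, f in zip(children, child_fitness)
    ]
    return new_pop


def train_ga(
    problem: Dataset,
    config: GAConfig,
    net_config: NetworkConfig,
    fitness: str = "GE",
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
) -> TrainResult:
    """Run the full GA from a random initial population.

    ``fitness`` selects the objective: "GE" (plain error) or "FIB"
    (single-fault-averaged error).  Training stops when the termination
    error of the best-by-fitness individual drops below
    ``config.error_tolerance``, or at ``config.max_generations``.  The
    initial random population counts as generation 1.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    fitness = fitness.upper()
    if fitness == "GE":
        fn = GEFitness(problem, net_config)
    elif fitness == "FIB":
        fn = FIBFitness(problem, net_config)
    else:
        raise ValueError("fitness must be 'GE' or 'FIB'")
    eq1 = GEFitness(problem, net_config)

    lo, hi = config.init_bounds
    genomes = rng.uniform(lo, hi, size=(config.pop_size, net_config.n_params))
    fits = _evaluate_batch(fn, genomes)
    pop = [Individual(genome=g, fitness=float(f)) for g, f in zip(genomes, fits)]

    trace = []
    reason = "max_iterations"
    terminated_at = config.max_generations
    for generation in range(1, config.max_generations + 1):
        if generation > 1:
            pop = evolve_generation(pop, fn, generation, config, rng)
        pop = rank_population(pop)
        best = min(pop, key=lambda ind: ind.rank)
        trace.append(best.fitness)
        stop_error = (
            best.fitness if config.stop_on == "fitness" else eq1(best.genome)
        )
        if stop_error < config.error_tolerance:
            reason = "tolerance"
            terminated_at = generation
            break

    best = min(pop, key=lambda ind: ind.rank)
    best_net = FeedforwardNet.from_vector(net_config, best.genome)
    return TrainResult(
        best_net=best_net,
        best_error_trace=np.array(trace),
        terminated_at=terminated_at if reason == "tolerance" else len(trace),
        termination_reason=reason,
        final_error=eq1(best.genome),
        seed=seed,
    )
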