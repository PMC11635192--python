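"""Genetic algorithm over integer DAC genomes, with elitism.

The optimizer treats the substrate as a black box: an individual is a
vector of integer DAC codes (2 genes for a homogeneous chain, 9 for a
five-compartment chain with per-circuit conductances), its fitness is a
non-negative score computed from a measurement on the substrate, and
smaller is better.  Each generation the n_elites fittest individuals are
copied unchanged, the remaining slots are filled by tournament
selection, and the selected individuals undergo one-point crossover of
consecutive pairs (probability p_cx) and per-gene power-of-two mutation
(individual picked with p_mut, each gene mutated with p_gen by adding or
subtracting 2^x, x uniform on 0..9, resampled while out of bounds).

Because the substrate is noisy, a re-measured individual can score
differently each time; with ``reevaluate_elites`` the elites are
re-measured every generation, reproducing the non-monotone best-fitness
traces seen on analog hardware despite elitism.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from . import experiment as xp
from .rng import stream
from .substrate import DAC_MAX, SubstrateConfig
from .experiment import (
    AmplitudeMatrix,
    FitError,
    Observation,
    ProtocolConfig,
    TargetObservation,
)

__all__ = [
    "WORST_FITNESS",
    "Individual",
    "GAConfig",
    "GenerationRecord",
    "GAResult",
    "EvolutionError",
    "fitness_lambda",
    "fitness_lambda_amplitude",
    "fitness_multisite",
    "init_population",
    "select_elites",
    "tournament_select",
    "one_point_crossover",
    "mutate_gene",
    "mutate_individual",
    "evolve",
    "make_evaluator",
]

#: Sentinel fitness for degenerate measurements (flat attenuation profiles
#: at extreme DAC corners); far above any achievable score so selection
#: stays total.
WORST_FITNESS = 1.0e6


class EvolutionError(ValueError):
    """Invalid GA configuration or population state."""


@dataclass
class Individual:
    """Integer DAC genome with an optional cached fitness (None =
    unevaluated; smaller fitness is better)."""

    genes: np.ndarray
    fitness: float | None = None

    def __post_init__(self) -> None:
        self.genes = np.asarray(self.genes, dtype=np.int64)
        if np.any(self.genes < 0) or np.any(self.genes > DAC_MAX):
            raise EvolutionError(f"genes must lie in [0, {DAC_MAX}]")

    def copy(self) -> "Individual":
        return Individual(genes=self.genes.copy(), fitness=self.fitness)


@dataclass(frozen=True)
class GAConfig:
    """Hyperparameters of the evolutionary loop.

    Defaults are the working set for this problem: population 50 with 5
    elites, 30 generations, one-point crossover at 50%, individual
    mutation at 10% with 50% per-gene rate, tournament size 3.
    """

    n_individuals: int = 50
    n_elites: int = 5
    n_generations: int = 30
    p_cx: float = 0.5
    p_mut: float = 0.1
    p_gen: float = 0.5
    tournament_k: int = 3
    fitness_mode: str = "lambda_only"
    seed: int = 0
    reevaluate_elites: bool = False
    stop_fitness: float | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.n_elites < self.n_individuals:
            raise EvolutionError("need 0 <= n_elites < n_individuals")
        for name in ("p_cx", "p_mut", "p_gen"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise EvolutionError(f"{name} must lie in [0, 1]")
        if self.tournament_k < 1:
            raise EvolutionError("tournament_k must be >= 1")
        if self.fitness_mode not in ("lambda_only", "lambda_and_h0", "multisite"):
            raise EvolutionError(f"unknown fitness_mode {self.fitness_mode!r}")

    @property
    def n_selection(self) -> int:
        return self.n_individuals - self.n_elites


@dataclass(frozen=True)
class GenerationRecord:
    generation: int
    genes: np.ndarray  # (n_individuals, n_genes)
    fitnesses: np.ndarray
    best_index: int
    best_genes: np.ndarray
    best_fitness: float
    mean_fitness: float


@dataclass
class GAResult:
    """Per-generation history plus the final best individual."""

    records: list[GenerationRecord]
    best: Individual
    config: GAConfig
    gene_count: int

    @property
    def n_generations_run(self) -> int:
        return len(self.records)


# --------------------------------------------------------------------------
# fitness functions
# --------------------------------------------------------------------------


def fitness_lambda(obs: Observation, target: TargetObservation) -> float:
    """f = |lambda_emp - lambda_hat|: distance to the target length
    constant, in compartments."""
    if target.lambda_hat is None:
        raise EvolutionError("target lambda_hat is not set")
    return abs(obs.lambda_emp - target.lambda_hat)


def fitness_lambda_amplitude(obs: Observation, target: TargetObservation) -> float:
    """f2 = ((lambda_hat - lambda)/lambda_hat)^2 + ((h0_hat - h0)/h0_hat)^2:
    sum of squared relative errors of both observables."""
    if target.lambda_hat is None or target.h0_hat is None:
        raise EvolutionError("target lambda_hat and h0_hat must be set")
    rel_lam = (target.lambda_hat - obs.lambda_emp) / target.lambda_hat
    rel_h0 = (target.h0_hat - obs.h0) / target.h0_hat
    return rel_lam**2 + rel_h0**2


def fitness_multisite(h: AmplitudeMatrix, h_hat: AmplitudeMatrix) -> float:
    """f3 = sum_ij (h_hat[i,j] - h[i,j])^2 over the amplitude matrix, bits^2."""
    if h.h.shape != h_hat.h.shape:
        raise EvolutionError("amplitude matrices must have the same shape")
    return float(np.sum((h_hat.h - h.h) ** 2))


# --------------------------------------------------------------------------
# operators
# --------------------------------------------------------------------------


def init_population(
    cfg: GAConfig, gene_count: int, rng: np.random.Generator
) -> list[Individual]:
    """n_individuals random genomes, each gene uniform on [0, 1022]."""
    if gene_count < 1:
        raise EvolutionError("gene_count must be >= 1")
    return [
        Individual(genes=rng.integers(0, DAC_MAX + 1, size=gene_count))
        for _ in range(cfg.n_individuals)
    ]


def select_elites(pop: Sequence[Individual], n_elites: int) -> list[Individual]:
    """Copies of the n_elites individuals with smallest fitness; ties are
    broken by population order (stable sort)."""
    if any(ind.fitness is None for ind in pop):
        raise EvolutionError("all individuals must be evaluated before elitism")
    order = sorted(range(len(pop)), key=lambda i: (pop[i].fitness, i))
    return [pop[i].copy() for i in order[:n_elites]]


def tournament_select(
    pop: Sequence[Individual],
    k: int,
    n_select: int,
    rng: np.random.Generator,
) -> list[Individual]:
    """n_select winners of independent k-tournaments.

    Each tournament draws k distinct individuals uniformly from the full
    population (elites included) and keeps the fittest; draws are with
    replacement across tournaments, so the same individual can win many.
    """
    if len(pop) == 0:
        raise EvolutionError("population is empty")
    if k > len(pop):
        raise EvolutionError("tournament size exceeds population")
    if any(ind.fitness is None for ind in pop):
        raise EvolutionError("all individuals must be evaluated before selection")
    winners = []
    for _ in range(n_select):
        idx = rng.choice(len(pop), size=k, replace=False)
        best = min(idx, key=lambda i: (pop[i].fitness, i))
        winners.append(pop[best].copy())
    return winners


def one_point_crossover(
    parent1: Individual, parent2: Individual, cut_point: int
) -> tuple[Individual, Individual]:
    """Swap the gene segments before ``cut_point`` between the parents.

    Offspring 1 takes parent 2's leading segment and parent 1's trailing
    one, and vice versa, e.g. parents (408, 139) and (364, 975) with
    cut 1 give (364, 139) and (408, 975).
    """
    g1, g2 = parent1.genes, parent2.genes
    if g1.size != g2.size or g1.size < 2:
        raise EvolutionError("parents must share a gene count >= 2")
    if not 1 <= cut_point <= g1.size - 1:
        raise EvolutionError(f"cut_point must lie in [1, {g1.size - 1}]")
    child1 = np.concatenate([g2[:cut_point], g1[cut_point:]])
    child2 = np.concatenate([g1[:cut_point], g2[cut_point:]])
    return Individual(genes=child1), Individual(genes=child2)


def mutate_gene(gene: int, rng: np.random.Generator) -> int:
    """Add or subtract 2^x (x uniform on 0..9, sign uniform); both are
    redrawn until the result lies within [0, 1022].  The result always
    differs from the input."""
    g = int(gene)
    if not 0 <= g <= DAC_MAX:
        raise EvolutionError(f"gene {g} outside [0, {DAC_MAX}]")
    while True:
        x = int(rng.integers(0, 10))
        sign = 1 if rng.integers(0, 2) else -1
        new = g + sign * (1 << x)
        if 0 <= new <= DAC_MAX:
            return new


def mutate_individual(
    ind: Individual, p_gen: float, rng: np.random.Generator
) -> Individual:
    """Mutate each gene independently with probability p_gen; the cached
    fitness is invalidated if anything changed."""
    out = ind.copy()
    changed = False
    for i in range(out.genes.size):
        if rng.random() < p_gen:
            out.genes[i] = mutate_gene(int(out.genes[i]), rng)
            changed = True
    if changed:
        out.fitness = None
    return out


# --------------------------------------------------------------------------
# evolutionary loop
# --------------------------------------------------------------------------

Evaluator = Callable[[np.ndarray, np.random.Generator], float]


def _record(pop: Sequence[Individual], generation: int) -> GenerationRecord:
    fit = np.array([ind.fitness for ind in pop], dtype=float)
    best = int(np.argmin(fit))
    return GenerationRecord(
        generation=generation,
        genes=np.stack([ind.genes for ind in pop]),
        fitnesses=fit,
        best_index=best,
        best_genes=pop[best].genes.copy(),
        best_fitness=float(fit[best]),
        mean_fitness=float(fit.mean()),
    )


def evolve(evaluator: Evaluator, cfg: GAConfig, gene_count: int) -> GAResult:
    """Run the generational loop and return the full history.

    ``evaluator(genes, rng)`` must return a non-negative fitness for any
    in-bounds genome (degenerate measurements map to WORST_FITNESS, not
    exceptions).  All randomness — initialization, selection, variation,
    and the evaluator's measurement noise — derives from ``cfg.seed``
    through named streams, so equal configs give identical results.  If
    ``cfg.stop_fitness`` is set the loop ends early once the best
    individual reaches it; otherwise exactly n_generations records are
    produced.
    """
    init_rng = stream(cfg.seed, "ga", "init")
    sel_rng = stream(cfg.seed, "ga", "select")
    var_rng = stream(cfg.seed, "ga", "vary")
    eval_rng = stream(cfg.seed, "ga", "evaluate")

    pop = init_population(cfg, gene_count, init_rng)
    records: list[GenerationRecord] = []

    for gen in range(1, cfg.n_generations + 1):
        for ind in pop:
            if ind.fitness is None:
                ind.fitness = float(evaluator(ind.genes, eval_rng))
        records.append(_record(pop, gen))
        best = records[-1]
        if cfg.stop_fitness is not None and best.best_fitness <= cfg.stop_fitness:
            break
        if gen == cfg.n_generations:
            break

        elites = select_elites(pop, cfg.n_elites)
        if cfg.reevaluate_elites:
            for e in elites:
                e.fitness = None
        selected = tournament_select(pop, cfg.tournament_k, cfg.n_selection, sel_rng)
        for i in range(0, len(selected) - 1, 2):
            if var_rng.random() < cfg.p_cx:
                cut = int(var_rng.integers(1, selected[i].genes.size))
                selected[i], selected[i + 1] = one_point_crossover(
                    selected[i], selected[i + 1], cut
                )
        selected = [
            mutate_individual(ind, cfg.p_gen, var_rng)
            if var_rng.random() < cfg.p_mut
            else ind
            for ind in selected
        ]
        pop = elites + selected

    final = records[-1]
    best_ind = Individual(genes=final.best_genes.copy(), fitness=final.best_fitness)
    return GAResult(records=records, best=best_ind, config=cfg, gene_count=gene_count)


# --------------------------------------------------------------------------
# substrate-backed evaluators
# --------------------------------------------------------------------------


def make_evaluator(
    fitness_mode: str,
    target: TargetObservation,
    substrate_cfg: SubstrateConfig,
    protocol_cfg: ProtocolConfig,
) -> Evaluator:
    """Build the measurement-backed fitness for the GA.

    Every call runs a fresh noisy experiment (a new measurement seed is
    drawn from the GA's evaluation stream, emulating independent runs on
    an analog substrate) and scores it against the target.  Degenerate
    attenuation fits return WORST_FITNESS.
    """

    def evaluate(genes: np.ndarray, rng: np.random.Generator) -> float:
        seed = int(rng.integers(0, 2**31))
        try:
            if fitness_mode == "multisite":
                h = xp.run_multisite_experiment(
                    genes, substrate_cfg, protocol_cfg, seed=seed
                )
                return fitness_multisite(h, target.h_hat)
            obs = xp.run_attenuation_experiment(
                genes, substrate_cfg, protocol_cfg, seed=seed
            )
        except FitError:
            return WORST_FITNESS
        if fitness_mode == "lambda_only":
            return fitness_lambda(obs, target)
        if fitness_mode == "lambda_and_h0":
            return fitness_lambda_amplitude(obs, target)
        raise EvolutionError(f"unknown fitness_mode {fitness_mode!r}")

    return evaluate
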