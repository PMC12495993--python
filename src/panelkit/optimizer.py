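"""Population-based genetic algorithm over gene panels.

The optimizer maintains a population of fixed-size, duplicate-free panels
drawn from a candidate gene pool. Each iteration scores every panel with
the multi-metric objective (memoized on panel content), carries the top
elite fraction unchanged into the next generation — so the best score
never decreases — and refills the rest by mutating randomly chosen elites
(replacing a few genes with fresh pool genes); an optional single-point
set-crossover of two elites can precede mutation. The run stops at the
iteration cap or when the best score has not improved by more than ``tol``
for ``patience`` consecutive iterations.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .core_data import DataValidationError, GenePanel

Objective = Callable[[GenePanel], float]


def dataset_objective(ds, db=None, graph=None, config=None) -> Objective:
    """Bind :func:`panelkit.scoring.ga_objective` to a dataset and inputs."""
    from . import scoring

    def objective(panel: GenePanel) -> float:
        return scoring.ga_objective(ds, panel, db=db, graph=graph, config=config)

    return objective


@dataclass
class GAConfig:
    candidate_pool: tuple[str, ...]
    population: int = 50
    panel_size: int = 200
    max_iters: int = 5000
    elite_fraction: float = 0.2
    mutation_genes: int | None = None  # default max(1, round(0.05 * panel_size))
    crossover_prob: float = 0.0
    patience: int = 200
    tol: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        self.candidate_pool = tuple(dict.fromkeys(self.candidate_pool))
        if self.mutation_genes is None:
            self.mutation_genes = max(1, round(0.05 * self.panel_size))
        if not 0 < self.elite_fraction < 1:
            raise DataValidationError("elite_fraction must be in (0, 1)")
        if self.panel_size > len(self.candidate_pool):
            raise DataValidationError("panel_size exceeds candidate pool size")
        if self.panel_size < 1 or self.population < 2 or self.max_iters < 1:
            raise DataValidationError("population, panel_size, max_iters must be positive")
        if self.mutation_genes < 1:
            raise DataValidationError("mutation_genes must be >= 1")
        if not 0 <= self.crossover_prob <= 1:
            raise DataValidationError("crossover_prob must be in [0, 1]")


@dataclass
class GAState:
    population: list[GenePanel]
    objectives: list[float]
    best_panel: GenePanel
    best_trajectory: list[float]
    mean_trajectory: list[float]
    iterations_run: int
    converged: bool
    seed: int
    cache: dict[frozenset, float] = field(default_factory=dict, repr=False)

    def to_json_dict(self) -> dict:
        return {
            "schema_version": 1,
            "best_panel": list(self.best_panel.genes),
            "best_objective": self.best_trajectory[-1],
            "best_trajectory": self.best_trajectory,
            "mean_trajectory": self.mean_trajectory,
            "iterations_run": self.iterations_run,
            "converged": self.converged,
            "seed": self.seed,
            "n_evaluated": len(self.cache),
        }


def mutate_panel(
    panel: GenePanel, pool: tuple[str, ...] | list[str], m: int, rng: np.random.Generator
) -> GenePanel:
    """Replace ``m`` uniformly chosen panel genes with fresh pool genes.

    Replacement genes are drawn uniformly from the pool minus the current
    panel, so the result keeps its size and stays duplicate-free. If fewer
    than ``m`` fresh genes exist, as many as possible are replaced, with a
    warning.
    """
    if m < 1 or m > len(panel):
        raise DataValidationError("m must satisfy 1 <= m <= panel size")
    current = list(panel.genes)
    outside = [g for g in pool if g not in set(current)]
    if len(outside) < m:
        warnings.warn(
            f"pool has only {len(outside)} genes outside the panel; replacing that many",
            stacklevel=2,
        )
        m = len(outside)
    if m == 0:
        return panel
    drop_idx = rng.choice(len(current), size=m, replace=False)
    new_genes = rng.choice(len(outside), size=m, replace=False)
    for pos, src in zip(sorted(drop_idx), new_genes):
        current[pos] = outside[src]
    return GenePanel(panel.name, tuple(current))


def _crossover(
    a: GenePanel, b: GenePanel, pool: tuple[str, ...], rng: np.random.Generator
) -> GenePanel:
    """Single-point set-crossover: prefix of a, then unseen genes of b.

    The child is trimmed/filled from the pool to the parents' size and kept
    duplicate-free.
    """
    size = len(a)
    cut = int(rng.integers(1, size)) if size > 1 else 1
    child = list(a.genes[:cut])
    seen = set(child)
    for g in b.genes:
        if len(child) == size:
            break
        if g not in seen:
            child.append(g)
            seen.add(g)
    if len(child) < size:
        filler = [g for g in pool if g not in seen]
        extra = rng.choice(len(filler), size=size - len(child), replace=False)
        child.extend(filler[i] for i in extra)
    return GenePanel(a.name, tuple(child[:size]))


def _random_panel(
    pool: tuple[str, ...], size: int, rng: np.random.Generator, name: str
) -> GenePanel:
    idx = rng.choice(len(pool), size=size, replace=False)
    return GenePanel(name, tuple(pool[i] for i in sorted(idx)))


def optimize_panel(objective: Objective, ga: GAConfig) -> GAState:
    """Run the elitist genetic algorithm; returns the full optimizer state.

    ``objective`` maps a :class:`GenePanel` to a score in [0, 1] (higher is
    better); :func:`panelkit.scoring.ga_objective` is the standard choice,
    but any callable may be injected. Evaluations are memoized on panel
    content, so re-scored survivors cost nothing.
    """
    rng = np.random.default_rng(ga.seed)
    cache: dict[frozenset, float] = {}

    def score(panel: GenePanel) -> float:
        key = frozenset(panel.genes)
        if key not in cache:
            cache[key] = float(objective(panel))
        return cache[key]

    population = [
        _random_panel(ga.candidate_pool, ga.panel_size, rng, f"ga_{i}")
        for i in range(ga.population)
    ]
    n_elite = math.ceil(ga.elite_fraction * ga.population)

    best_traj: list[float] = []
    mean_traj: list[float] = []
    stale = 0
    converged = False
    iterations = 0
    objs = [score(p) for p in population]

    for iteration in range(ga.max_iters):
        iterations = iteration + 1
        order = np.argsort(objs)[::-1]
        population = [population[i] for i in order]
        objs = [objs[i] for i in order]
        best = objs[0]
        prev_best = best_traj[-1] if best_traj else -np.inf
        best_traj.append(best)
        mean_traj.append(float(np.mean(objs)))

        if best - prev_best > ga.tol:
            stale = 0
        else:
            stale += 1
        if stale >= ga.patience:
            converged = True
            break
        if iteration == ga.max_iters - 1:
            break

        elites = population[:n_elite]
        children: list[GenePanel] = []
        while len(children) < ga.population - n_elite:
            if ga.crossover_prob > 0 and rng.random() < ga.crossover_prob and n_elite >= 2:
                pa, pb = rng.choice(n_elite, size=2, replace=False)
                base = _crossover(elites[pa], elites[pb], ga.candidate_pool, rng)
            else:
                base = elites[int(rng.integers(n_elite))]
            children.append(
                mutate_panel(base, ga.candidate_pool, ga.mutation_genes, rng)
            )
        population = list(elites) + children
        objs = [score(p) for p in population]

    order = np.argsort(objs)[::-1]
    population = [population[i] for i in order]
    objs = [objs[i] for i in order]
    best_panel = GenePanel("ga_best", population[0].genes)
    return GAState(
        population=population,
        objectives=objs,
        best_panel=best_panel,
        best_trajectory=best_traj,
        mean_trajectory=mean_traj,
        iterations_run=iterations,
        converged=converged,
        seed=ga.seed,
        cache=cache,
    )
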