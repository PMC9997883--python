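"""Genetic algorithm over motility parameters.

A (mu + lambda) evolutionary scheme: each of the N_pop individuals produces
lambda offspring by log-normal mutation of its parameters, all
(lambda + 1) * N_pop individuals (parents included) are re-evaluated with a
fresh stochastic simulation, and the N_pop fittest survive. The mutation
width sigma_mut is 0.6 for the first five generations (helping populations
drift off the initial fitness plateau) and 0.2 afterwards.

The engine is generic over the fitness function, so the same machinery
drives the Act-CPM cells and the Beauchemin reference model.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .lattice import Genotype, PhysicalParams, free_params, skin_params
from .migration import run_simulation
from .tissue import EnvironmentSpec, SetupError, build_environment

#: (max_act, lambda_act) points along the free-environment evolutionary
#: trajectory at which motion statistics are measured.
TRAJECTORY_POINTS: tuple[tuple[float, float], ...] = (
    (5, 5),
    (50, 17),
    (110, 30),
    (70, 150),
    (50, 1185),
)

#: Consensus evolved optima: free environment, skin, and free started from
#: the higher lambda_act = 100.
FREE_OPTIMUM = (50.0, 1165.0)
SKIN_OPTIMUM = (55.0, 1190.0)
FREE_FROM_HIGH_LAMBDA_OPTIMUM = (50.0, 1190.0)


@dataclass
class EvolutionConfig:
    """Settings of one evolutionary run."""

    initial_params: tuple[float, ...] = (5.0, 5.0)
    param_names: tuple[str, ...] = ("max_act", "lambda_act")
    n_pop: int = 10
    n_offspring: int = 3  # lambda offspring per parent
    generations: int = 50
    sigma_early: float = 0.6
    sigma_late: float = 0.2
    sigma_switch: int = 5  # generations run at sigma_early
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pop < 1 or self.n_offspring < 1:
            raise ValueError("population and offspring counts must be >= 1")
        if self.sigma_early < 0 or self.sigma_late < 0:
            raise ValueError("mutation widths must be >= 0")
        if len(self.initial_params) != len(self.param_names):
            raise ValueError("initial_params and param_names length mismatch")
        if any(p <= 0 for p in self.initial_params):
            raise ValueError("initial parameters must be strictly positive")

    def sigma_at(self, generation: int) -> float:
        """Mutation width for a 0-based generation index."""
        return self.sigma_early if generation < self.sigma_switch else self.sigma_late


@dataclass
class EvolutionHistory:
    """Per-generation record of all evaluated individuals of one run.

    ``table`` has one row per evaluated individual with columns
    ``run, generation, individual, parent, <param columns>, fitness, broken,
    survivor``. Generations are 1-based in the table.
    """

    table: pd.DataFrame
    config: EvolutionConfig
    run: int = 0

    @property
    def generations(self) -> int:
        return int(self.table["generation"].max())

    def survivors(self, generation: int) -> pd.DataFrame:
        g = self.table
        return g[(g["generation"] == generation) & g["survivor"]]

    def population_mean(self, param: str) -> pd.Series:
        """Arithmetic mean of a parameter over survivors, per generation."""
        surv = self.table[self.table["survivor"]]
        return surv.groupby("generation")[param].mean()

    def best_fitness(self) -> pd.Series:
        return self.table.groupby("generation")["fitness"].max()


def mutate(
    params: Sequence[float] | np.ndarray, sigma: float, rng: np.random.Generator
) -> np.ndarray:
    """Log-normal mutation: each value x becomes exp(ln x + eps), eps ~ N(0, sigma).

    Operating on the log scale keeps every parameter strictly positive and
    makes mutation steps relative rather than absolute.
    """
    x = np.asarray(params, dtype=float)
    if np.any(x <= 0):
        raise ValueError("parameters must be strictly positive")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return x.copy()
    return np.exp(np.log(x) + rng.normal(0.0, sigma, size=x.shape))


def next_generation(
    population: list[np.ndarray],
    evaluate: Callable[[np.ndarray, np.random.Generator], dict],
    config: EvolutionConfig,
    rng: np.random.Generator,
    generation: int = 0,
) -> tuple[list[np.ndarray], pd.DataFrame]:
    """One GA step: mutate, evaluate everyone afresh, keep the N_pop fittest.

    ``evaluate`` maps (parameter vector, child rng) to a dict with at least a
    ``fitness`` key. Parents persist unmutated among the candidates and are
    re-evaluated like everyone else. Ties in fitness are broken by a uniform
    random order drawn from ``rng``. Returns the survivor parameter vectors
    and the evaluation table for this generation.
    """
    if len(population) != config.n_pop:
        raise ValueError(f"expected a population of {config.n_pop}")
    sigma = config.sigma_at(generation)
    candidates: list[np.ndarray] = []
    parents: list[int] = []
    for i, parent in enumerate(population):
        candidates.append(np.asarray(parent, dtype=float).copy())
        parents.append(i)
        for _ in range(config.n_offspring):
            candidates.append(mutate(parent, sigma, rng))
            parents.append(i)
    rows = []
    for j, cand in enumerate(candidates):
        child_rng = np.random.default_rng(rng.integers(2**31))
        result = evaluate(cand, child_rng)
        row = {
            "generation": generation + 1,
            "individual": j,
            "parent": parents[j],
            "fitness": float(result["fitness"]),
            "broken": bool(result.get("broken", False)),
        }
        for name, value in zip(config.param_names, cand):
            row[name] = float(value)
        rows.append(row)
    table = pd.DataFrame(rows)
    tiebreak = rng.permutation(len(table))
    order = np.lexsort((tiebreak, -table["fitness"].to_numpy()))
    survivor_idx = order[: config.n_pop]
    table["survivor"] = False
    table.loc[table.index[survivor_idx], "survivor"] = True
    survivors = [candidates[i] for i in survivor_idx]
    return survivors, table


def run_evolution(
    config: EvolutionConfig,
    evaluate: Callable[[np.ndarray, np.random.Generator], dict] | None = None,
    run: int = 0,
) -> EvolutionHistory:
    """Run the full GA for ``config.generations`` generations.

    Without an explicit ``evaluate``, an Act-CPM free-environment evaluator
    at full scale is used (see :func:`make_act_evaluator`).
    """
    if evaluate is None:
        evaluate = make_act_evaluator()
    rng = np.random.default_rng(config.seed)
    population = [np.asarray(config.initial_params, dtype=float)] * config.n_pop
    tables = []
    for g in range(config.generations):
        population, table = next_generation(population, evaluate, config, rng, g)
        tables.append(table)
    full = pd.concat(tables, ignore_index=True)
    full.insert(0, "run", run)
    return EvolutionHistory(table=full, config=config, run=run)


def make_act_evaluator(
    env: str = "free",
    params: PhysicalParams | None = None,
    width: int = 150,
    height: int = 150,
    eval_mcs: int = 10_000,
    burnin: int = 500,
    log_interval: int = 5,
) -> Callable[[np.ndarray, np.random.Generator], dict]:
    """Fitness function for Act-CPM genotypes: explored area per simulation.

    Builds a fresh environment per individual (seed drawn from the child
    rng), runs the migration simulation and returns the fitness record.
    Setup failures and annihilations yield fitness 0.
    """
    if params is None:
        params = free_params() if env == "free" else skin_params()
    spec = EnvironmentSpec(kind=env, width=width, height=height, burnin=burnin)

    def evaluate(param_vec: np.ndarray, rng: np.random.Generator) -> dict:
        genotype = Genotype(max_act=param_vec[0], lambda_act=param_vec[1])
        try:
            state = build_environment(spec, params, genotype, rng)
        except SetupError:
            return {"fitness": 0.0, "broken": True}
        track, record = run_simulation(
            state, genotype, params, duration=eval_mcs, log_interval=log_interval, rng=rng
        )
        return {
            "fitness": record.fitness,
            "broken": record.broken or record.annihilated,
        }

    return evaluate


def estimate_optimum(
    histories: Sequence[EvolutionHistory],
    window: int = 10,
    change_threshold: float = 0.2,
    round_to: float = 5.0,
    mode: str = "either",
) -> tuple[float, ...]:
    """Consensus optimum across runs: log-scale mean of late survivors.

    Runs that have not converged are dropped: a run is removed if the
    population mean of a parameter changes by at least ``change_threshold``
    (relative) between generations G-window+1 and G. ``mode='either'`` drops
    the run when either parameter moved (the stricter reading);
    ``mode='both'`` only when all did. Survivor parameter values from the
    last ``window`` generations of the remaining runs are pooled, averaged
    on the log scale, and rounded to the nearest ``round_to``.
    """
    if not histories:
        raise ValueError("need at least one history")
    if mode not in ("either", "both"):
        raise ValueError("mode must be 'either' or 'both'")
    names = histories[0].config.param_names
    kept = []
    for hist in histories:
        last = hist.generations
        if last < window:
            raise ValueError(f"histories need >= {window} generations")
        first = last - window + 1
        moved = []
        for name in names:
            means = hist.population_mean(name)
            rel = abs(means.loc[last] - means.loc[first]) / means.loc[first]
            moved.append(rel >= change_threshold)
        dropped = any(moved) if mode == "either" else all(moved)
        if not dropped:
            kept.append((hist, first, last))
    if not kept:
        raise ValueError("all runs dropped by the convergence filter")
    result = []
    for name in names:
        pooled = np.concatenate(
            [
                h.table[
                    h.table["survivor"] & h.table["generation"].between(first, last)
                ][name].to_numpy()
                for h, first, last in kept
            ]
        )
        log_mean = np.exp(np.log(pooled).mean())
        result.append(round_to * np.round(log_mean / round_to))
    return tuple(float(v) for v in result)


def sweep_points(
    optimum: tuple[float, float], i_max: int = 3, step: float = 0.1
) -> list[Genotype]:
    """Cross-shaped genotype sweep around an optimum.

    ``{(max_act^i, lambda_act*)} U {(max_act*, lambda_act^i)}`` with
    ``x^i = exp(ln x* +/- i * step)``, i in 0..i_max; the centre is counted
    once, giving ``4 * i_max + 1`` points (13 by default).
    """
    ma, la = optimum
    if ma <= 0 or la <= 0:
        raise ValueError("optimum must be strictly positive")
    points = [Genotype(ma, la)]
    for i in range(1, i_max + 1):
        for sign in (1.0, -1.0):
            points.append(Genotype(float(np.exp(np.log(ma) + sign * i * step)), la))
            points.append(Genotype(ma, float(np.exp(np.log(la) + sign * i * step))))
    return points
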