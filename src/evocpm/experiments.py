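"""Desk-scale experiment presets.

Full replication of the evolutionary endpoints (10 runs x 50 generations x
40 individuals x 10,000 MCS) is an overnight, embarrassingly parallel
computation. The functions here run the same machinery at reduced problem
sizes — smaller grid, shorter evaluations, fewer generations — chosen so the
qualitative evolutionary trends (rising motility parameters and fitness in
the Act-CPM; rising speed/run-length and falling pause time in the
run-and-pause model) are reproducible on a single core in minutes.
"""
from __future__ import annotations

import pandas as pd

from .beauchemin import beauchemin_config, evolve_beauchemin
from .evolution import EvolutionConfig, EvolutionHistory, make_act_evaluator, run_evolution


def scaled_free_evolution(
    seed: int,
    run: int = 0,
    width: int = 100,
    height: int = 100,
    eval_mcs: int = 2000,
    generations: int = 15,
) -> EvolutionHistory:
    """One scaled-down free-environment evolutionary run from (5, 5)."""
    cfg = EvolutionConfig(
        initial_params=(5.0, 5.0), generations=generations, seed=seed
    )
    evaluator = make_act_evaluator(
        env="free", width=width, height=height, eval_mcs=eval_mcs
    )
    return run_evolution(cfg, evaluator, run=run)


def free_evolution_trend(n_seeds: int = 10, seed: int = 0, **kwargs) -> pd.DataFrame:
    """Scaled free-environment evolution over several independent runs.

    Returns one row per run with the initial and final population means of
    max_act and lambda_act, the initial and final best fitness, and boolean
    trend flags (did each quantity increase?).
    """
    rows = []
    for r in range(n_seeds):
        hist = scaled_free_evolution(seed=seed + r, run=r, **kwargs)
        mm = hist.population_mean("max_act")
        ml = hist.population_mean("lambda_act")
        bf = hist.best_fitness()
        init = hist.config.initial_params
        rows.append(
            {
                "run": r,
                "max_act_final": mm.iloc[-1],
                "lambda_act_final": ml.iloc[-1],
                "best_fitness_initial": bf.iloc[0],
                "best_fitness_final": bf.iloc[-1],
                "max_act_increased": bool(mm.iloc[-1] > init[0]),
                "lambda_act_increased": bool(ml.iloc[-1] > init[1]),
                "fitness_increased": bool(bf.iloc[-1] > bf.iloc[0]),
            }
        )
    return pd.DataFrame(rows)


def beauchemin_trend(
    n_runs: int = 10,
    seed: int = 0,
    duration: int = 2000,
    generations: int = 25,
) -> pd.DataFrame:
    """Run-and-pause evolution over several runs; per-run trend flags.

    The expected directions: v_free and t_free increase (faster, straighter
    motion covers more area), t_pause decreases (pausing never helps).
    """
    rows = []
    for r in range(n_runs):
        cfg = beauchemin_config(seed=seed + r, generations=generations)
        hist = evolve_beauchemin(cfg, duration=duration, run=r)
        finals = {p: hist.population_mean(p).iloc[-1] for p in cfg.param_names}
        bf = hist.best_fitness()
        rows.append(
            {
                "run": r,
                **{f"{p}_final": v for p, v in finals.items()},
                "best_fitness_initial": bf.iloc[0],
                "best_fitness_final": bf.iloc[-1],
                "v_free_up": bool(finals["v_free"] > 1.0),
                "t_free_up": bool(finals["t_free"] > 1.0),
                "t_pause_down": bool(finals["t_pause"] < 1.0),
                "fitness_increased": bool(bf.iloc[-1] > bf.iloc[0]),
            }
        )
    return pd.DataFrame(rows)
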