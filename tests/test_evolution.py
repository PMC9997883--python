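"""Genetic-algorithm machinery: mutation, selection, consensus, sweeps."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from evocpm.evolution import (
    FREE_OPTIMUM,
    SKIN_OPTIMUM,
    TRAJECTORY_POINTS,
    EvolutionConfig,
    EvolutionHistory,
    estimate_optimum,
    mutate,
    next_generation,
    run_evolution,
    sweep_points,
)


class _FixedNormal:
    """Stand-in rng returning a fixed normal deviate."""

    def __init__(self, eps):
        self.eps = eps

    def normal(self, loc, scale, size=None):
        return np.full(size, self.eps * (scale / abs(scale) if scale else 0.0)) \
            if size else self.eps


class TestMutate:
    def test_zero_sigma_is_identity(self, rng):
        out = mutate([5.0, 5.0], 0.0, rng)
        assert out.tolist() == [5.0, 5.0]

    def test_known_deviate_scales_by_exp(self):
        # x = 5 with eps = +0.6 -> 5 * e^0.6 ~ 9.111
        out = mutate([5.0], 0.6, _FixedNormal(0.6))
        assert out[0] == pytest.approx(5 * np.exp(0.6))
        assert out[0] == pytest.approx(9.111, abs=5e-4)

    def test_log_ratio_statistics_match_sigma(self, rng):
        """ln(x_mut / x) has mean ~0 and SD ~sigma over many draws."""
        sigma = 0.37
        ratios = np.log(mutate(np.full(100_000, 3.0), sigma, rng) / 3.0)
        assert ratios.mean() == pytest.approx(0.0, abs=0.006)
        assert ratios.std() == pytest.approx(sigma, rel=0.02)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        st.lists(st.floats(1e-6, 1e6), min_size=1, max_size=4),
        st.floats(0, 3),
        st.integers(0, 2**31 - 1),
    )
    def test_output_always_strictly_positive(self, xs, sigma, seed):
        out = mutate(xs, sigma, np.random.default_rng(seed))
        assert np.all(out > 0)

    def test_non_positive_input_rejected(self, rng):
        with pytest.raises(ValueError):
            mutate([0.0, 5.0], 0.2, rng)


def _rank_evaluator(values):
    """Deterministic fitness: looks up by rounded parameter value."""

    def evaluate(params, rng):
        return {"fitness": float(values.get(round(params[0], 6), params[0]))}

    return evaluate


class TestNextGeneration:
    def test_ten_fittest_of_forty_survive(self, rng):
        cfg = EvolutionConfig(initial_params=(1.0,), param_names=("p",), seed=0)
        population = [np.array([float(i + 1)]) for i in range(10)]

        def evaluate(params, child_rng):
            return {"fitness": float(params[0])}

        # sigma 0 => offspring identical to parents; distinct fitnesses come
        # from the parent values themselves
        cfg_frozen = EvolutionConfig(
            initial_params=(1.0,), param_names=("p",),
            sigma_early=0.0, sigma_late=0.0, seed=0,
        )
        survivors, table = next_generation(population, evaluate, cfg_frozen, rng)
        assert len(table) == 40
        top = sorted(table["fitness"], reverse=True)[:10]
        assert sorted((s[0] for s in survivors), reverse=True) == top
        # monotone selection: worst survivor >= best non-survivor
        assert table[table["survivor"]]["fitness"].min() >= \
            table[~table["survivor"]]["fitness"].max()

    def test_all_broken_population_still_yields_ten_survivors(self, rng):
        cfg = EvolutionConfig(initial_params=(1.0,), param_names=("p",), seed=0)
        population = [np.array([1.0])] * 10

        def evaluate(params, child_rng):
            return {"fitness": 0.0, "broken": True}

        survivors, table = next_generation(population, evaluate, cfg, rng)
        assert len(survivors) == 10
        assert (table["fitness"] == 0).all()
        assert table["survivor"].sum() == 10

    def test_same_seed_gives_identical_survivors(self):
        def evaluate(params, child_rng):
            return {"fitness": float(child_rng.random())}

        outs = []
        for _ in range(2):
            rng = np.random.default_rng(99)
            cfg = EvolutionConfig(initial_params=(2.0, 3.0), seed=0)
            pop = [np.array([2.0, 3.0])] * 10
            survivors, table = next_generation(pop, evaluate, cfg, rng)
            outs.append(table)
        pd.testing.assert_frame_equal(outs[0], outs[1])


class TestRunEvolution:
    def test_history_shape_and_positivity(self):
        cfg = EvolutionConfig(initial_params=(5.0, 5.0), generations=6, seed=1)

        def evaluate(params, child_rng):
            return {"fitness": float(params.sum() + child_rng.random())}

        hist = run_evolution(cfg, evaluate)
        assert hist.generations == 6
        assert len(hist.table) == 6 * 40
        assert (hist.table[["max_act", "lambda_act"]] > 0).all().all()
        per_gen = hist.table.groupby("generation")["survivor"].sum()
        assert (per_gen == 10).all()

    def test_sigma_schedule_switches_after_five_generations(self):
        cfg = EvolutionConfig()
        assert [cfg.sigma_at(g) for g in (0, 4, 5, 10)] == [0.6, 0.6, 0.2, 0.2]


def _history_from_means(mean_by_gen, n=10, params=("max_act", "lambda_act")):
    """Synthetic history whose survivors all sit at the given means."""
    rows = []
    for gen, values in mean_by_gen.items():
        for i in range(n):
            row = {"run": 0, "generation": gen, "individual": i, "parent": 0,
                   "fitness": 1.0, "broken": False, "survivor": True}
            for p, v in zip(params, values):
                row[p] = v
            rows.append(row)
    cfg = EvolutionConfig(initial_params=(5.0, 5.0), generations=max(mean_by_gen))
    return EvolutionHistory(table=pd.DataFrame(rows), config=cfg)


class TestEstimateOptimum:
    def test_constant_run_returns_its_values(self):
        hist = _history_from_means({g: (50.0, 1165.0) for g in range(1, 13)})
        assert estimate_optimum([hist]) == (50.0, 1165.0)

    def test_log_mean_then_round_to_five(self):
        # equal numbers of 45 and 55 pooled -> exp(mean(ln)) ~ 49.75 -> 50
        rows = []
        for gen in range(1, 11):
            for i in range(10):
                v = 45.0 if i < 5 else 55.0  # constant population mean of 50
                rows.append({"run": 0, "generation": gen, "individual": i,
                             "parent": 0, "max_act": v, "lambda_act": v,
                             "fitness": 1.0, "broken": False, "survivor": True})
        cfg = EvolutionConfig(initial_params=(5.0, 5.0), generations=10)
        hist = EvolutionHistory(table=pd.DataFrame(rows), config=cfg)
        out = estimate_optimum([hist])
        assert out[0] == 50.0
        raw = np.exp(0.5 * (np.log(45) + np.log(55)))
        assert raw == pytest.approx(49.749, abs=5e-4)

    def test_non_converged_run_is_dropped(self):
        moving = {g: (50.0, 5.0 * g) for g in range(1, 13)}  # lambda_act 5 -> 500
        stable = {g: (50.0, 1165.0) for g in range(1, 13)}
        hist_m = _history_from_means(moving)
        hist_s = _history_from_means(stable)
        assert estimate_optimum([hist_s, hist_m]) == (50.0, 1165.0)
        with pytest.raises(ValueError):
            estimate_optimum([hist_m])  # all runs dropped

    def test_both_mode_keeps_single_parameter_drift(self):
        moving = {g: (50.0, 5.0 * g) for g in range(1, 13)}
        hist_m = _history_from_means(moving)
        # with mode='both' the run survives because max_act did not move
        out = estimate_optimum([hist_m], mode="both")
        assert out[0] == 50.0


class TestSweepPoints:
    def test_thirteen_distinct_points_with_centre_once(self):
        pts = sweep_points((50.0, 1165.0))
        assert len(pts) == 13
        assert len({(p.max_act, p.lambda_act) for p in pts}) == 13

    def test_offset_arithmetic(self):
        pts = sweep_points((50.0, 1165.0))
        max_acts = sorted({p.max_act for p in pts})
        assert max(max_acts) == pytest.approx(50 * np.exp(0.3))
        assert max(max_acts) == pytest.approx(67.49, abs=5e-3)
        assert min(max_acts) == pytest.approx(50 * np.exp(-0.3))

    def test_centre_is_the_optimum(self):
        pts = sweep_points((70.0, 150.0))
        assert (pts[0].max_act, pts[0].lambda_act) == (70.0, 150.0)


class TestPresets:
    def test_trajectory_points_available(self):
        assert TRAJECTORY_POINTS == ((5, 5), (50, 17), (110, 30), (70, 150), (50, 1185))

    def test_evolved_optima_available(self):
        assert FREE_OPTIMUM == (50.0, 1165.0)
        assert SKIN_OPTIMUM == (55.0, 1190.0)
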