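"""The Beauchemin run-and-pause random walk and its evolution.

A constraint-free reference model: a point cell alternates straight "runs"
of duration ``t_free`` at speed ``v_free`` (direction uniform on the circle,
redrawn after each pause) with stationary pauses of duration ``t_pause``.
Unlike the Act-CPM, the model parameters map directly onto speed and
persistence, so evolution under an area-coverage fitness simply pushes
``v_free`` and ``t_free`` up and ``t_pause`` down.

Fitness discretises space: at every sampled time point, all integer lattice
points within radius ``r`` of the cell's position are marked, and the
fitness is the number of distinct marked points divided by the disc area
``pi r^2``. The default ``r = 13`` gives a disc of about 530 lattice points,
matching the Act-CPM cell area.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .evolution import EvolutionConfig, EvolutionHistory, run_evolution
from .migration import Track


@dataclass(frozen=True)
class BeaucheminParams:
    """Run-and-pause walk parameters (all strictly positive)."""

    v_free: float  # speed during runs, pixels per time step
    t_free: float  # run duration, time steps
    t_pause: float  # pause duration, time steps

    def __post_init__(self) -> None:
        if not (self.v_free > 0 and self.t_free > 0 and self.t_pause > 0):
            raise ValueError("Beauchemin parameters must be strictly positive")


def simulate_beauchemin(
    params: BeaucheminParams,
    duration: int = 10_000,
    dt: float = 1.0,
    rng: np.random.Generator | None = None,
    track_id: int = 0,
) -> Track:
    """Simulate a run-and-pause walk, sampled at ``dt``-spaced time points.

    The walk starts with a run (first direction drawn at t = 0) and
    alternates runs and pauses in continuous time; sampled positions
    interpolate linearly within runs. Returns a track of
    ``duration/dt + 1`` points starting at the origin.
    """
    if rng is None:
        rng = np.random.default_rng()
    total = duration * dt if dt != 1.0 else float(duration)
    cycle = params.t_free + params.t_pause
    n_cycles = int(np.ceil(total / cycle)) + 1
    angles = rng.uniform(0.0, 2.0 * np.pi, size=n_cycles)
    run_dx = params.v_free * params.t_free * np.cos(angles)
    run_dy = params.v_free * params.t_free * np.sin(angles)
    # node times: 0, t_free, t_free+t_pause, 2 t_free+t_pause, ...
    node_t = np.empty(2 * n_cycles + 1)
    node_x = np.empty(2 * n_cycles + 1)
    node_y = np.empty(2 * n_cycles + 1)
    node_t[0] = 0.0
    node_x[0] = 0.0
    node_y[0] = 0.0
    node_t[1::2] = np.arange(n_cycles) * cycle + params.t_free
    node_t[2::2] = (np.arange(n_cycles) + 1) * cycle
    node_x[1::2] = np.cumsum(run_dx)
    node_x[2::2] = node_x[1::2]  # pauses: position constant
    node_y[1::2] = np.cumsum(run_dy)
    node_y[2::2] = node_y[1::2]
    sample_t = np.arange(duration + 1) * dt
    x = np.interp(sample_t, node_t, node_x)
    y = np.interp(sample_t, node_t, node_y)
    return Track(t=sample_t, x=x, y=y, track_id=track_id)


# -- disc-coverage fitness -------------------------------------------------

_EMPTY64 = np.int64(-(1 << 62))


@njit(cache=True)
def _covered_count(xs, ys, r, keys, stamps, epoch):
    """Count distinct integer points within distance r of any sampled position.

    ``keys``/``stamps`` form an open-addressing hash table (capacity a power
    of two) reused across calls via the ``epoch`` stamp. Points already
    covered by the immediately preceding position are skipped without a
    table lookup (they were inserted then).
    """
    cap = len(keys)
    mask = cap - 1
    r2 = r * r
    count = 0
    px = 0.0
    py = 0.0
    for i in range(len(xs)):
        x = xs[i]
        y = ys[i]
        ix_lo = int(np.ceil(x - r))
        ix_hi = int(np.floor(x + r))
        for ix in range(ix_lo, ix_hi + 1):
            rem = r2 - (ix - x) * (ix - x)
            if rem < 0.0:
                continue
            dy = np.sqrt(rem)
            iy_lo = int(np.ceil(y - dy))
            iy_hi = int(np.floor(y + dy))
            for iy in range(iy_lo, iy_hi + 1):
                if i > 0:
                    ddx = ix - px
                    ddy = iy - py
                    if ddx * ddx + ddy * ddy <= r2:
                        continue  # already inserted at the previous position
                key = (np.int64(ix) << 32) ^ (np.int64(iy) & np.int64(0xFFFFFFFF))
                slot = int((np.uint64(key) * np.uint64(0x9E3779B97F4A7C15)) >> np.uint64(32)) & mask
                while True:
                    if stamps[slot] != epoch:
                        stamps[slot] = epoch
                        keys[slot] = key
                        count += 1
                        break
                    if keys[slot] == key:
                        break
                    slot = (slot + 1) & mask
        px = x
        py = y
    return count


class _VisitedTable:
    """Reusable hash table for disc-coverage counting."""

    def __init__(self):
        self.keys = np.zeros(0, dtype=np.int64)
        self.stamps = np.zeros(0, dtype=np.int64)
        self.epoch = 0

    def arrays(self, capacity_hint: int):
        cap = 1
        while cap < capacity_hint:
            cap *= 2
        if cap > len(self.keys):
            self.keys = np.full(cap, _EMPTY64, dtype=np.int64)
            self.stamps = np.zeros(cap, dtype=np.int64)
            self.epoch = 0
        self.epoch += 1
        return self.keys, self.stamps, self.epoch


_SHARED_TABLE = _VisitedTable()


def covered_lattice_points(track: Track, r: float = 13.0) -> int:
    """Number of distinct integer lattice points within ``r`` of the track."""
    if r <= 0:
        raise ValueError("r must be > 0")
    xs = np.ascontiguousarray(track.x, dtype=np.float64)
    ys = np.ascontiguousarray(track.y, dtype=np.float64)
    disc = np.pi * r * r
    path = float(np.hypot(np.diff(xs), np.diff(ys)).sum())
    # coverage is bounded both by a corridor around the path and by one
    # full disc per sampled position, whichever is smaller
    bound = int(min(disc + (2 * r + 3) * (path + 1), (disc + 4 * r + 4) * len(xs))) + 64
    keys, stamps, epoch = _SHARED_TABLE.arrays(2 * bound)
    return int(_covered_count(xs, ys, float(r), keys, stamps, epoch))


def disc_fitness(track: Track, r: float = 13.0) -> float:
    """Explored area in cell-area units: covered lattice points / (pi r^2)."""
    return covered_lattice_points(track, r) / (np.pi * r * r)


# -- evolution -------------------------------------------------------------

def beauchemin_config(seed: int = 0, generations: int = 25) -> EvolutionConfig:
    """GA configuration of the reference-model experiment.

    Same machinery as the Act-CPM runs (N_pop = 10, lambda = 3, sigma_mut
    0.6 for five generations then 0.2) but over (v_free, t_free, t_pause)
    from (1, 1, 1), and only 25 generations — fitness plateaus once
    consecutive discs stop overlapping.
    """
    return EvolutionConfig(
        initial_params=(1.0, 1.0, 1.0),
        param_names=("v_free", "t_free", "t_pause"),
        generations=generations,
        seed=seed,
    )


def make_beauchemin_evaluator(duration: int = 10_000, r: float = 13.0):
    """Fitness function: disc-coverage of a fresh simulated walk."""

    def evaluate(param_vec: np.ndarray, rng: np.random.Generator) -> dict:
        params = BeaucheminParams(*param_vec)
        track = simulate_beauchemin(params, duration=duration, rng=rng)
        return {"fitness": disc_fitness(track, r), "broken": False}

    return evaluate


def evolve_beauchemin(
    config: EvolutionConfig | None = None,
    duration: int = 10_000,
    r: float = 13.0,
    seed: int = 0,
    run: int = 0,
) -> EvolutionHistory:
    """Evolve the run-and-pause parameters under the disc-coverage fitness."""
    if config is None:
        config = beauchemin_config(seed=seed)
    return run_evolution(config, make_beauchemin_evaluator(duration, r), run=run)
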