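"""Environment construction: empty ("free") space and packed "skin" tissue.

The free environment is a single T cell burned in for 500 MCS on an empty
150x150 torus. The skin environment packs 31 keratinocytes onto the same
torus: cells are seeded one at a time at random free positions with a tight
perimeter target of 200 (keeping them round while growing), each given
50 MCS to grow before the next is placed; after a further 500 MCS of
equilibration the first-seeded keratinocyte is replaced by the T cell and
the keratinocytes receive their final perimeter target of 330.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .engine import CpmSimulation, disc_offsets
from .lattice import (
    BACKGROUND,
    KERATINOCYTE,
    TCELL,
    Genotype,
    LatticeState,
    PhysicalParams,
    skin_params,
)


class SetupError(RuntimeError):
    """A cell was lost (annihilated) while building the environment."""


@dataclass
class EnvironmentSpec:
    """Configuration of one of the two study environments."""

    kind: str = "free"  # "free" | "skin"
    width: int = 150
    height: int = 150
    burnin: int = 500
    n_keratinocytes: int = 31
    growth_interval: int = 50  # MCS between successive keratinocyte seeds
    seeding_perimeter: float = 200.0
    final_perimeter: float = 330.0
    seed_volume: int = 25  # initial painted footprint of each cell seed

    def __post_init__(self) -> None:
        if self.kind not in ("free", "skin"):
            raise ValueError(f"unknown environment kind {self.kind!r}")
        if self.kind == "skin" and self.n_keratinocytes < 1:
            raise ValueError("skin requires at least one keratinocyte")


def init_free(
    params: PhysicalParams,
    genotype: Genotype,
    rng: np.random.Generator,
    width: int = 150,
    height: int = 150,
    burnin: int = 500,
) -> LatticeState:
    """One T cell seeded at the grid centre, then burned in.

    The cell is painted as a compact disc of its target volume and given
    ``burnin`` MCS to relax its volume and shape. Raises :class:`SetupError`
    if the cell annihilates during burn-in.
    """
    sim = _free_simulation(params, genotype, rng, width, height, burnin)
    return sim.state()


def _free_simulation(params, genotype, rng, width=150, height=150, burnin=500):
    seed = int(rng.integers(2**31))
    sim = CpmSimulation(width, height, params, genotype, seed=seed)
    target = int(params.target_volume[TCELL])
    sim.seed_cell_disc((width // 2, height // 2), target, TCELL)
    sim.advance(burnin)
    if sim.volume(1) == 0:
        raise SetupError("T cell annihilated during burn-in")
    return sim


def init_skin(
    spec: EnvironmentSpec | None,
    params: PhysicalParams | None,
    genotype: Genotype,
    rng: np.random.Generator,
) -> LatticeState:
    """Packed keratinocyte tissue with one embedded T cell.

    Returns a state containing ``n_keratinocytes - 1`` keratinocytes and one
    T cell (the first-seeded keratinocyte's pixels, reassigned). Raises
    :class:`SetupError` if any cell annihilates during setup; callers may
    retry with a fresh seed.
    """
    if spec is None:
        spec = EnvironmentSpec(kind="skin")
    if params is None:
        params = skin_params()
    seed = int(rng.integers(2**31))
    grow_params = params.copy()
    grow_params.target_perimeter[KERATINOCYTE] = spec.seeding_perimeter
    sim = CpmSimulation(spec.width, spec.height, grow_params, genotype=None, seed=seed)
    for k in range(spec.n_keratinocytes):
        center = _free_position(sim, spec.seed_volume, rng)
        sim.seed_cell_disc(center, spec.seed_volume, KERATINOCYTE)
        sim.advance(spec.growth_interval)
        _check_cells(sim, k + 1)
    sim.advance(spec.burnin)
    _check_cells(sim, spec.n_keratinocytes)
    final_params = params.copy()
    final_params.target_perimeter[KERATINOCYTE] = spec.final_perimeter
    sim.set_params(final_params)
    sim.convert_cell(1, TCELL)  # first-seeded keratinocyte becomes the T cell
    sim.set_genotype(genotype)
    return sim.state()


def _check_cells(sim: CpmSimulation, expected: int) -> None:
    alive = int(np.count_nonzero(sim.volumes))
    if alive != expected:
        raise SetupError(
            f"cell annihilated during skin setup ({alive}/{expected} alive)"
        )


def _free_position(
    sim: CpmSimulation, seed_volume: int, rng: np.random.Generator, attempts: int = 2000
):
    """Uniform random position whose seed footprint is entirely background."""
    offs = disc_offsets(seed_volume)
    w, h = sim.width, sim.height
    for _ in range(attempts):
        cx = int(rng.integers(w))
        cy = int(rng.integers(h))
        xs = (offs[:, 0] + cx) % w
        ys = (offs[:, 1] + cy) % h
        if np.all(sim.ids[xs, ys] == BACKGROUND):
            return cx, cy
    # dense grid: enumerate all valid positions and draw one uniformly
    valid = []
    for cx in range(w):
        for cy in range(h):
            xs = (offs[:, 0] + cx) % w
            ys = (offs[:, 1] + cy) % h
            if np.all(sim.ids[xs, ys] == BACKGROUND):
                valid.append((cx, cy))
    if not valid:
        raise SetupError("no free position left for a keratinocyte seed")
    return valid[int(rng.integers(len(valid)))]


def build_environment(
    spec: EnvironmentSpec,
    params: PhysicalParams,
    genotype: Genotype,
    rng: np.random.Generator,
) -> LatticeState:
    """Dispatch to :func:`init_free` or :func:`init_skin` based on the spec."""
    if spec.kind == "free":
        return init_free(
            params, genotype, rng, spec.width, spec.height, spec.burnin
        )
    return init_skin(spec, params, genotype, rng)
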