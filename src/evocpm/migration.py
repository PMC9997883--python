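"""Single-cell migration runs: track logging, exploration fitness, breakage.

A simulation advances a prepared environment for a fixed number of MCS,
logging the T cell's centroid every ``log_interval`` MCS (coordinates
unwrapped across the torus). Fitness is the total area the cell ever
occupied, in units of the 500-pixel target cell volume; it drops to zero if
the cell "breaks" (connectedness below 0.9 at any checkpoint) or loses all
its pixels.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernel as K
from .engine import CpmSimulation
from .lattice import Genotype, LatticeState, PhysicalParams, TCELL

BREAK_THRESHOLD = 0.9
FITNESS_AREA = 500.0  # one T-cell volume, the fitness unit


@dataclass
class Track:
    """Time-ordered centroid positions of one simulated cell."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    track_id: int = 0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.t) == len(self.x) == len(self.y)):
            raise ValueError("t, x, y must have equal length")
        if len(self.t) >= 2:
            dt = np.diff(self.t)
            if np.any(dt <= 0) or not np.allclose(dt, dt[0]):
                raise ValueError("times must strictly increase with constant spacing")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0]) if len(self.t) >= 2 else np.nan

    def positions(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])


@dataclass
class FitnessRecord:
    """Per-simulation fitness ingredients."""

    explored_pixels: int
    fitness: float
    min_connectedness: float
    broken: bool
    annihilated: bool = False


def connectedness(pixels, shape: tuple[int, int] | None = None, periodic: bool = True) -> float:
    """Probability that two random pixels of a cell share a connected component.

    ``C = sum_k (n_k / N)^2`` over Moore-connected components of sizes
    ``n_k``. Accepts a boolean mask (with ``periodic`` wrap-around on its
    shape) or an iterable of ``(x, y)`` pixels; pixel sets are embedded in a
    padded non-periodic box unless ``shape`` is given.
    """
    if isinstance(pixels, np.ndarray) and pixels.dtype == bool:
        mask = pixels
    else:
        pts = np.asarray(list(pixels), dtype=int)
        if pts.size == 0:
            raise ValueError("connectedness of an empty pixel set is undefined")
        if shape is None:
            # pad by one so components never touch across the wrap
            pts = pts - pts.min(axis=0) + 1
            shape = tuple(pts.max(axis=0) + 2)
            periodic = False
        mask = np.zeros(shape, dtype=bool)
        mask[pts[:, 0] % shape[0], pts[:, 1] % shape[1]] = True
    if not mask.any():
        raise ValueError("connectedness of an empty pixel set is undefined")
    ids = mask.astype(np.int32)
    if not periodic:
        ids = np.pad(ids, 1)  # a border of zeros breaks the torus adjacency
    labels = np.zeros_like(ids)
    stack = np.zeros(ids.size, dtype=np.int64)
    return float(K.connectedness_kernel(ids, 1, labels, stack))


def centroid(
    state: LatticeState,
    cell_id: int,
    previous_centroid: tuple[float, float] | None = None,
) -> tuple[float, float]:
    """Torus-consistent centroid of a cell.

    Computed with the minimal-image convention relative to
    ``previous_centroid`` (or to the cell's first pixel if absent), so cells
    straddling the periodic boundary get a geometrically sensible centre.
    """
    ids = np.asarray(state.identity if isinstance(state, LatticeState) else state)
    if previous_centroid is None:
        pix = np.argwhere(ids == cell_id)
        if len(pix) == 0:
            raise ValueError(f"cell {cell_id} has no pixels")
        previous_centroid = (float(pix[0, 0]), float(pix[0, 1]))
    dx, dy, n = K.centroid_kernel(
        ids.astype(np.int32), cell_id, float(previous_centroid[0]), float(previous_centroid[1])
    )
    if n == 0:
        raise ValueError(f"cell {cell_id} has no pixels")
    return previous_centroid[0] + dx, previous_centroid[1] + dy


def run_simulation(
    state: LatticeState,
    genotype: Genotype,
    params: PhysicalParams,
    duration: int = 10_000,
    log_interval: int = 5,
    rng: np.random.Generator | None = None,
    track_id: int = 0,
    check_every_mcs: bool = False,
) -> tuple[Track, FitnessRecord]:
    """Advance a prepared environment and log the T cell's migration.

    The centroid is logged every ``log_interval`` MCS (the first point at
    t = 0); every pixel the T cell ever occupies counts towards the explored
    area. Connectedness is evaluated at every log point (every MCS if
    ``check_every_mcs``); a minimum below 0.9 marks the cell broken and
    zeroes the fitness, as does annihilation.
    """
    if rng is None:
        rng = np.random.default_rng()
    tcell_ids = np.nonzero(np.asarray(state.cell_kind) == TCELL)[0]
    present = [cid for cid in tcell_ids if np.any(state.identity == cid)]
    if len(present) != 1:
        raise ValueError(f"state must contain exactly one T cell, found {len(present)}")
    cid = int(present[0])
    sim = CpmSimulation.from_state(state, params, genotype, seed=int(rng.integers(2**31)))
    sim.start_exploration(cid)

    n_logs = duration // log_interval
    times = np.empty(n_logs + 1)
    xs = np.empty(n_logs + 1)
    ys = np.empty(n_logs + 1)

    pix = np.argwhere(sim.ids == cid)
    ref = (float(pix[0, 0]), float(pix[0, 1]))
    dx, dy, _ = sim.centroid_offset(cid, ref)
    ux, uy = ref[0] + dx, ref[1] + dy  # unwrapped position
    wrapped = (ux % sim.width, uy % sim.height)
    times[0], xs[0], ys[0] = 0.0, ux, uy
    min_c = sim.connectedness(cid)
    annihilated = False
    n_logged = 1

    chunk = 1 if check_every_mcs else log_interval
    for step in range(1, n_logs + 1):
        for _ in range(log_interval // chunk):
            sim.advance(chunk)
            if sim.volume(cid) == 0:
                annihilated = True
                break
            if check_every_mcs:
                c = sim.connectedness(cid)
                if c < min_c:
                    min_c = c
        if annihilated:
            break
        dx, dy, _ = sim.centroid_offset(cid, wrapped)
        ux, uy = ux + dx, uy + dy
        wrapped = (ux % sim.width, uy % sim.height)
        times[step], xs[step], ys[step] = step * log_interval, ux, uy
        n_logged += 1
        if not check_every_mcs:
            c = sim.connectedness(cid)
            if c < min_c:
                min_c = c

    track = Track(times[:n_logged], xs[:n_logged], ys[:n_logged], track_id=track_id)
    broken = bool(min_c < BREAK_THRESHOLD)
    explored = sim.explored_pixels
    fitness = 0.0 if (broken or annihilated) else explored / FITNESS_AREA
    record = FitnessRecord(
        explored_pixels=explored,
        fitness=fitness,
        min_connectedness=float(min_c),
        broken=broken,
        annihilated=annihilated,
    )
    return track, record
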