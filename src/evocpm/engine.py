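"""Simulation driver: a stateful wrapper around the numba CPM kernel.

:class:`CpmSimulation` owns the lattice arrays plus the incremental
bookkeeping (per-cell volumes and perimeters, border-pixel list, explored
mask) and exposes stepping, seeding and measurement methods. It can be built
from scratch or from a :class:`~evocpm.lattice.LatticeState`, and converted
back at any time.

Each simulation carries its own RNG state (xorshift128+), seeded from a
single integer, so runs are reproducible and independent of global state.
"""
from __future__ import annotations

import numpy as np

from . import _kernel as K
from .lattice import (
    BACKGROUND,
    TCELL,
    Genotype,
    LatticeState,
    PhysicalParams,
)


def disc_offsets(volume: int) -> np.ndarray:
    """Offsets of a compact disc of exactly ``volume`` pixels around (0, 0).

    Pixels are ranked by distance from the centre (ties broken by
    coordinates) and the closest ``volume`` are kept, yielding a deterministic
    near-circular seed shape.
    """
    r = int(np.ceil(np.sqrt(volume / np.pi))) + 2
    xs, ys = np.mgrid[-r : r + 1, -r : r + 1]
    d2 = xs**2 + ys**2
    order = np.lexsort((ys.ravel(), xs.ravel(), d2.ravel()))
    return np.column_stack([xs.ravel()[order], ys.ravel()[order]])[:volume]


class CpmSimulation:
    """A running Act-CPM simulation on a periodic grid."""

    def __init__(
        self,
        width: int,
        height: int,
        params: PhysicalParams,
        genotype: Genotype | None = None,
        seed: int = 0,
        max_cells: int = 64,
    ):
        self.width = int(width)
        self.height = int(height)
        self.params = params
        self.ids = np.zeros((width, height), dtype=np.int32)
        self.gain = np.full((width, height), K.GAIN_NEVER, dtype=np.int64)
        self.mismatch = np.zeros((width, height), dtype=np.int32)
        self.border_list = np.zeros(width * height, dtype=np.int64)
        self.border_pos = np.full((width, height), -1, dtype=np.int64)
        self.scalars = np.zeros(8, dtype=np.int64)
        self.scalars[K.SC_ANNIHILATED] = -1
        self.volumes = np.zeros(max_cells, dtype=np.int64)
        self.perims = np.zeros(max_cells, dtype=np.int64)
        self.cell_kind = np.zeros(max_cells, dtype=np.int8)
        self.explored = np.zeros((width, height), dtype=np.uint8)
        self.explored_cell = -1
        self._labels = np.zeros((width, height), dtype=np.int32)
        self._stack = np.zeros(width * height, dtype=np.int64)
        self.rng_state = np.zeros(2, dtype=np.uint64)
        K.seed_rng_state(int(seed), self.rng_state)
        self.set_genotype(genotype)
        self._sync_params()

    # -- construction ------------------------------------------------------

    @classmethod
    def from_state(
        cls,
        state: LatticeState,
        params: PhysicalParams,
        genotype: Genotype | None = None,
        seed: int = 0,
    ) -> "CpmSimulation":
        max_cells = max(64, len(state.cell_kind))
        sim = cls(state.width, state.height, params, genotype, seed, max_cells)
        sim.ids[:, :] = state.identity
        n = len(state.cell_kind)
        sim.cell_kind[:n] = state.cell_kind
        # reconstruct gain times from the activity snapshot: a pixel with
        # activity a of a cell with memory m was gained (m - a) MCS ago
        for cid in state.cell_ids():
            if sim.cell_kind[cid] != TCELL or genotype is None:
                continue
            mask = state.identity == cid
            act = state.activity[mask]
            g = np.full(act.shape, K.GAIN_NEVER, dtype=np.int64)
            pos = act > 0
            g[pos] = np.round(act[pos] - genotype.max_act).astype(np.int64)
            sim.gain[mask] = g
        sim.rebuild()
        return sim

    def rebuild(self) -> None:
        """Recompute all incremental bookkeeping from the identity grid."""
        K.build_geometry(
            self.ids,
            self.mismatch,
            self.border_list,
            self.border_pos,
            self.scalars,
            self.volumes,
            self.perims,
        )

    def seed_cell_disc(self, center: tuple[int, int], volume: int, kind: int) -> int:
        """Paint a compact disc of ``volume`` pixels as a new cell.

        All covered pixels must currently be background. Returns the new cell
        id. ``rebuild()`` is called automatically.
        """
        cid = int(self.volumes[1:].nonzero()[0][-1]) + 2 if self.volumes[1:].any() else 1
        if cid >= len(self.volumes):
            raise ValueError("max_cells exceeded")
        offs = disc_offsets(volume)
        xs = (offs[:, 0] + center[0]) % self.width
        ys = (offs[:, 1] + center[1]) % self.height
        if np.any(self.ids[xs, ys] != BACKGROUND):
            raise ValueError("seed footprint overlaps an existing cell")
        self.ids[xs, ys] = cid
        self.cell_kind[cid] = kind
        self.rebuild()
        return cid

    # -- parameters --------------------------------------------------------

    def set_genotype(self, genotype: Genotype | None) -> None:
        """Install the T cell's Act parameters (None disables the feedback)."""
        self.genotype = genotype
        n_kind = 3
        self._lam_act = np.zeros(n_kind)
        self._max_act = np.zeros(n_kind)
        if genotype is not None:
            self._lam_act[TCELL] = genotype.lambda_act
            self._max_act[TCELL] = genotype.max_act

    def _sync_params(self) -> None:
        p = self.params
        self._v_star = np.asarray(p.target_volume, dtype=np.float64)
        self._lam_v = np.asarray(p.lambda_volume, dtype=np.float64)
        self._p_star = np.asarray(p.target_perimeter, dtype=np.float64)
        self._lam_p = np.asarray(p.lambda_perimeter, dtype=np.float64)
        self._adhesion = np.asarray(p.adhesion, dtype=np.float64)

    def set_params(self, params: PhysicalParams) -> None:
        self.params = params
        self._sync_params()

    def convert_cell(self, cid: int, kind: int) -> None:
        """Change a cell's kind in place (e.g. keratinocyte -> T cell).

        The cell's activity is reset to zero; it acquires the target
        volume/perimeter and adhesion of its new kind immediately.
        """
        self.cell_kind[cid] = kind
        self.gain[self.ids == cid] = K.GAIN_NEVER

    # -- stepping ----------------------------------------------------------

    def advance(self, n_mcs: int) -> None:
        K.advance_kernel(
            self.ids,
            self.gain,
            self.mismatch,
            self.border_list,
            self.border_pos,
            self.scalars,
            self.volumes,
            self.perims,
            self.cell_kind,
            self._v_star,
            self._lam_v,
            self._p_star,
            self._lam_p,
            self._adhesion,
            self._lam_act,
            self._max_act,
            float(self.params.temperature),
            int(n_mcs),
            self.explored,
            int(self.explored_cell),
            self.rng_state,
        )

    # -- measurement -------------------------------------------------------

    @property
    def time(self) -> int:
        """Current simulation time in MCS."""
        return int(self.scalars[K.SC_T])

    @property
    def annihilated_cell(self) -> int | None:
        cid = int(self.scalars[K.SC_ANNIHILATED])
        return None if cid < 0 else cid

    def volume(self, cid: int) -> int:
        return int(self.volumes[cid])

    def cell_ids(self) -> np.ndarray:
        return np.nonzero(self.volumes)[0]

    def connectedness(self, cid: int) -> float:
        return float(K.connectedness_kernel(self.ids, cid, self._labels, self._stack))

    def centroid_offset(self, cid: int, ref: tuple[float, float]):
        """Minimal-image centroid displacement from ``ref``; (dx, dy, n)."""
        return K.centroid_kernel(self.ids, cid, float(ref[0]), float(ref[1]))

    def start_exploration(self, cid: int) -> None:
        """Begin explored-area accounting: the current footprint counts."""
        self.explored_cell = int(cid)
        self.explored[:, :] = (self.ids == cid).astype(np.uint8)
        self.scalars[K.SC_EXPLORED] = int(self.explored.sum())

    @property
    def explored_pixels(self) -> int:
        return int(self.scalars[K.SC_EXPLORED])

    def activity_grid(self) -> np.ndarray:
        """Current per-pixel activity, reconstructed from gain times."""
        act = np.zeros((self.width, self.height))
        t = self.time
        for cid in self.cell_ids():
            ma = self._max_act[self.cell_kind[cid]]
            if ma <= 0:
                continue
            mask = self.ids == cid
            a = ma - (t - self.gain[mask])
            act[mask] = np.clip(a, 0.0, None)
        return act

    def state(self) -> LatticeState:
        return LatticeState(
            self.ids.copy(), self.activity_grid(), self.cell_kind.copy()
        )
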