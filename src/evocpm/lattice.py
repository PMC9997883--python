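"""Lattice state and physical parameters of the 2D cellular Potts model (CPM).

A CPM configuration lives on a periodic ``width x height`` pixel grid. Every
pixel carries a cell id (0 = background / medium) and a real-valued
"protrusive activity" that decays by one per Monte Carlo step (MCS). Cells
belong to one of three kinds: background, T cell, or keratinocyte; physical
parameters (adhesion energies, volume and perimeter constraints) are defined
per kind, following the convention of multi-cell-kind CPM engines.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

# cell-kind indices
BACKGROUND = 0
TCELL = 1
KERATINOCYTE = 2

#: Moore neighbourhood offsets (8-connectivity), fixed scan order.
MOORE_OFFSETS = np.array(
    [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)],
    dtype=np.int64,
)


@dataclass(frozen=True)
class Genotype:
    """The evolvable parameter pair of the Act protrusion feedback.

    ``max_act`` (in MCS) sets how long a newly gained pixel keeps elevated
    activity, i.e. the memory of the protrusion; ``lambda_act`` (energy) sets
    the strength of the protrusive feedback relative to the other forces on
    the cell. Both are kept strictly positive: mutation acts on the log scale.
    """

    max_act: float
    lambda_act: float

    def __post_init__(self) -> None:
        if not (self.max_act > 0 and self.lambda_act > 0):
            raise ValueError(
                f"genotype values must be strictly positive, got "
                f"({self.max_act}, {self.lambda_act})"
            )

    def as_array(self) -> np.ndarray:
        return np.array([self.max_act, self.lambda_act], dtype=float)


@dataclass
class PhysicalParams:
    """Per-cell-kind CPM energy parameters (dimensionless CPM units).

    Arrays are indexed by cell kind ``[background, T cell, keratinocyte]``.
    ``adhesion[a, b]`` is the energy paid per unlike-cell Moore neighbour pair
    of kinds ``a`` and ``b``; it must be symmetric with zero
    background-background entry. Background has no volume or perimeter
    constraint (its lambdas are zero).
    """

    temperature: float = 20.0
    target_volume: np.ndarray = field(
        default_factory=lambda: np.array([0.0, 500.0, 750.0])
    )
    lambda_volume: np.ndarray = field(
        default_factory=lambda: np.array([0.0, 30.0, 30.0])
    )
    target_perimeter: np.ndarray = field(
        default_factory=lambda: np.array([0.0, 260.0, 330.0])
    )
    lambda_perimeter: np.ndarray = field(
        default_factory=lambda: np.array([0.0, 2.0, 10.0])
    )
    adhesion: np.ndarray = field(
        default_factory=lambda: np.array(
            [[0.0, 20.0, 20.0], [20.0, 20.0, 2.0], [20.0, 2.0, 200.0]]
        )
    )

    def __post_init__(self) -> None:
        self.target_volume = np.asarray(self.target_volume, dtype=float)
        self.lambda_volume = np.asarray(self.lambda_volume, dtype=float)
        self.target_perimeter = np.asarray(self.target_perimeter, dtype=float)
        self.lambda_perimeter = np.asarray(self.lambda_perimeter, dtype=float)
        self.adhesion = np.asarray(self.adhesion, dtype=float)
        if np.any(self.lambda_volume < 0) or np.any(self.lambda_perimeter < 0):
            raise ValueError("constraint strengths (lambda) must be >= 0")
        if not np.allclose(self.adhesion, self.adhesion.T):
            raise ValueError("adhesion matrix must be symmetric")
        if self.adhesion[BACKGROUND, BACKGROUND] != 0:
            raise ValueError("background-background adhesion must be 0")
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")

    def copy(self) -> "PhysicalParams":
        return replace(
            self,
            target_volume=self.target_volume.copy(),
            lambda_volume=self.lambda_volume.copy(),
            target_perimeter=self.target_perimeter.copy(),
            lambda_perimeter=self.lambda_perimeter.copy(),
            adhesion=self.adhesion.copy(),
        )


def free_params() -> PhysicalParams:
    """Parameters of the "free" (empty-space) environment.

    T cell: target volume 500 (lambda 30), target perimeter 260 (lambda 2),
    cell-background adhesion 20, temperature 20. Keratinocyte entries are
    present but unused in this environment.
    """
    return PhysicalParams()


def skin_params() -> PhysicalParams:
    """Parameters of the "skin" (packed keratinocyte) environment.

    T cell as in :func:`free_params`; keratinocytes: target volume 750,
    target perimeter 330 (lambda 10), keratinocyte-keratinocyte adhesion 200,
    T-cell-keratinocyte adhesion 2, cell-background adhesion 20.
    """
    return PhysicalParams()


@dataclass
class LatticeState:
    """A CPM grid snapshot: pixel identities plus per-pixel activity.

    ``identity[x, y]`` holds the owning cell id (0 = background) and
    ``activity[x, y]`` the remaining protrusive activity in MCS; background
    pixels always have activity 0. ``cell_kind[cid]`` maps each cell id to its
    cell kind. The grid is a torus.
    """

    identity: np.ndarray
    activity: np.ndarray
    cell_kind: np.ndarray

    def __post_init__(self) -> None:
        self.identity = np.asarray(self.identity, dtype=np.int32)
        self.activity = np.asarray(self.activity, dtype=np.float64)
        self.cell_kind = np.asarray(self.cell_kind, dtype=np.int8)
        if self.identity.shape != self.activity.shape:
            raise ValueError("identity and activity grids must share a shape")
        if self.identity.max(initial=0) >= len(self.cell_kind):
            raise ValueError("cell_kind table too short for the ids present")

    @property
    def width(self) -> int:
        return self.identity.shape[0]

    @property
    def height(self) -> int:
        return self.identity.shape[1]

    def cell_ids(self) -> np.ndarray:
        """Ids of all non-background cells present on the grid."""
        ids = np.unique(self.identity)
        return ids[ids > 0]

    def volume(self, cell_id: int) -> int:
        return int(np.count_nonzero(self.identity == cell_id))

    def pixels(self, cell_id: int) -> np.ndarray:
        """(n, 2) array of the pixels belonging to ``cell_id``."""
        return np.argwhere(self.identity == cell_id)

    def kind_of(self, cell_id: int) -> int:
        return int(self.cell_kind[cell_id])

    def copy(self) -> "LatticeState":
        return LatticeState(
            self.identity.copy(), self.activity.copy(), self.cell_kind.copy()
        )

    def validate(self, genotype: Genotype | None = None) -> None:
        """Check the state invariants; raise ``ValueError`` on violation."""
        if np.any(self.activity < 0):
            raise ValueError("negative activity")
        if np.any(self.activity[self.identity == BACKGROUND] != 0):
            raise ValueError("background pixels must have zero activity")
        if genotype is not None:
            acts = self.activity[self.cell_kind[self.identity] == TCELL]
            if np.any(acts > genotype.max_act + 1e-9):
                raise ValueError("activity exceeds max_act")


def empty_state(width: int, height: int, max_cells: int = 64) -> LatticeState:
    """An all-background torus with room for ``max_cells`` cell ids."""
    return LatticeState(
        np.zeros((width, height), dtype=np.int32),
        np.zeros((width, height), dtype=np.float64),
        np.zeros(max_cells, dtype=np.int8),
    )


def moore_neighbors(p: tuple[int, int], state: LatticeState | tuple[int, int]):
    """The 8 Moore neighbours of pixel ``p`` with periodic wrap-around.

    ``state`` may be a :class:`LatticeState` or a plain ``(width, height)``
    shape tuple. Always returns 8 distinct pixels (grids larger than 2x2).
    """
    if isinstance(state, LatticeState):
        w, h = state.width, state.height
    else:
        w, h = state
    x, y = p
    if not (0 <= x < w and 0 <= y < h):
        raise ValueError(f"pixel {p} outside a {w}x{h} grid")
    return [((x + dx) % w, (y + dy) % h) for dx, dy in MOORE_OFFSETS]
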