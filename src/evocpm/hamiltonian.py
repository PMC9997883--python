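"""Reference implementation of the Act-CPM energy and dynamics.

This module is the readable, brute-force-checkable definition of the model:

* the global Hamiltonian ``H = H_adhesion + H_volume + H_perimeter`` with
  quadratic volume/perimeter constraints ``lambda_X (X - X*)^2``;
* the local energy difference ``delta_h_physical`` of a single copy attempt,
  which must equal the brute-force difference of the global Hamiltonian;
* the Act protrusion feedback ``delta_h_act = -(lambda_act / max_act) *
  (GM_act(source) - GM_act(target))``, where ``GM_act(p)`` is the geometric
  mean of the activities of ``p`` and its same-cell Moore neighbours;
* Metropolis copy attempts and the Monte Carlo step (one sweep of
  ``width x height`` attempts followed by an activity decay of 1 per pixel).

It is deliberately simple and slow; production simulations run through the
numba kernel in :mod:`evocpm._kernel`, which is cross-validated against this
module in the test suite.
"""
from __future__ import annotations

import numpy as np

from .lattice import (
    BACKGROUND,
    MOORE_OFFSETS,
    Genotype,
    LatticeState,
    PhysicalParams,
    moore_neighbors,
)

__all__ = [
    "total_hamiltonian",
    "cell_perimeter",
    "delta_h_physical",
    "gm_act",
    "delta_h_act",
    "metropolis_accept",
    "attempt_copy",
    "apply_copy",
    "mcs_step",
]


def cell_perimeter(state: LatticeState, cell_id: int) -> int:
    """Perimeter of a cell: count of Moore pairs (p in cell, q not in cell)."""
    ids = state.identity
    mask = ids == cell_id
    total = 0
    for dx, dy in MOORE_OFFSETS:
        total += int(np.count_nonzero(mask & (np.roll(ids, (-dx, -dy), (0, 1)) != cell_id)))
    return total


def total_hamiltonian(state: LatticeState, params: PhysicalParams) -> float:
    """Global adhesion + volume + perimeter energy of a lattice state.

    The Act term is a pure ``delta H`` contribution (it has no stored global
    counterpart) and is therefore not part of this total.
    """
    ids = state.identity
    kinds = state.cell_kind
    h = 0.0
    # adhesion: each unordered unlike-id Moore pair counted once
    for dx, dy in MOORE_OFFSETS[:4]:  # half of the 8 directions
        shifted = np.roll(ids, (-dx, -dy), (0, 1))
        unlike = ids != shifted
        if np.any(unlike):
            h += params.adhesion[
                kinds[ids[unlike]], kinds[shifted[unlike]]
            ].sum()
    for cid in state.cell_ids():
        k = kinds[cid]
        v = state.volume(cid)
        h += params.lambda_volume[k] * (v - params.target_volume[k]) ** 2
        p = cell_perimeter(state, cid)
        h += params.lambda_perimeter[k] * (p - params.target_perimeter[k]) ** 2
    return float(h)


def delta_h_physical(
    state: LatticeState,
    source: tuple[int, int],
    target: tuple[int, int],
    params: PhysicalParams,
) -> float:
    """Energy change of copying the source pixel's id into the target pixel.

    Covers adhesion, volume and perimeter; equals
    ``total_hamiltonian(after) - total_hamiltonian(before)`` exactly.
    """
    ids = state.identity
    kinds = state.cell_kind
    new_id = int(ids[source])
    old_id = int(ids[target])
    if new_id == old_id:
        raise ValueError("source and target belong to the same cell")
    kn, ko = int(kinds[new_id]), int(kinds[old_id])
    dh = 0.0
    n_new = n_old = 0
    for q in moore_neighbors(target, state):
        rid = int(ids[q])
        if rid != new_id:
            dh += params.adhesion[kn, kinds[rid]]
        else:
            n_new += 1
        if rid != old_id:
            dh -= params.adhesion[ko, kinds[rid]]
        else:
            n_old += 1
    if new_id != BACKGROUND:
        v = state.volume(new_id)
        vs = params.target_volume[kn]
        dh += params.lambda_volume[kn] * ((v + 1 - vs) ** 2 - (v - vs) ** 2)
        p = cell_perimeter(state, new_id)
        ps = params.target_perimeter[kn]
        dp = 8 - 2 * n_new
        dh += params.lambda_perimeter[kn] * ((p + dp - ps) ** 2 - (p - ps) ** 2)
    if old_id != BACKGROUND:
        v = state.volume(old_id)
        vs = params.target_volume[ko]
        dh += params.lambda_volume[ko] * ((v - 1 - vs) ** 2 - (v - vs) ** 2)
        p = cell_perimeter(state, old_id)
        ps = params.target_perimeter[ko]
        dp = 2 * n_old - 8
        dh += params.lambda_perimeter[ko] * ((p + dp - ps) ** 2 - (p - ps) ** 2)
    return float(dh)


def gm_act(state: LatticeState, p: tuple[int, int]) -> float:
    """Geometric mean of activity over ``p`` and its same-cell Moore neighbours.

    Background pixels have GM_act 0, and a single zero activity in the
    included set forces the mean to 0 (protrusions cannot spread from
    inactive regions).
    """
    cid = int(state.identity[p])
    if cid == BACKGROUND:
        return 0.0
    values = [float(state.activity[p])]
    for q in moore_neighbors(p, state):
        if int(state.identity[q]) == cid:
            values.append(float(state.activity[q]))
    values = np.array(values)
    if np.any(values <= 0):
        return 0.0
    return float(np.exp(np.log(values).mean()))


def delta_h_act(
    state: LatticeState,
    source: tuple[int, int],
    target: tuple[int, int],
    genotype: Genotype | None,
) -> float:
    """Act feedback energy: ``-(lambda_act/max_act) (GM_act(s) - GM_act(t))``.

    Negative (favourable) when the source neighbourhood is more active than
    the target's: recently protruded regions are more likely to protrude
    again. With ``genotype=None`` or ``max_act == 0`` the feedback is
    disabled and the term is 0.
    """
    if int(state.identity[source]) == int(state.identity[target]):
        raise ValueError("source and target belong to the same cell")
    if genotype is None or genotype.max_act == 0:
        return 0.0
    gm_s = gm_act(state, source)
    gm_t = gm_act(state, target)
    return -(genotype.lambda_act / genotype.max_act) * (gm_s - gm_t)


def metropolis_accept(dh: float, temperature: float, rng: np.random.Generator) -> bool:
    """Metropolis rule: accept if ``dh <= 0``, else with prob ``exp(-dh/T)``."""
    if dh <= 0:
        return True
    return bool(rng.random() < np.exp(-dh / temperature))


def apply_copy(
    state: LatticeState,
    source: tuple[int, int],
    target: tuple[int, int],
    genotype: Genotype | None,
) -> None:
    """Execute a successful copy: target takes the source's identity.

    The target's activity is set to the gaining cell's ``max_act`` (0 if the
    gaining side is background or has no Act feedback).
    """
    new_id = int(state.identity[source])
    state.identity[target] = new_id
    from .lattice import TCELL

    if (
        new_id != BACKGROUND
        and genotype is not None
        and state.cell_kind[new_id] == TCELL
    ):
        state.activity[target] = genotype.max_act
    else:
        state.activity[target] = 0.0


def attempt_copy(
    state: LatticeState,
    rng: np.random.Generator,
    params: PhysicalParams,
    genotype: Genotype | None = None,
) -> bool:
    """One copy attempt: uniform source pixel, uniform Moore neighbour target.

    Returns True if the attempt changed the state. Attempts within a single
    cell (or background-background) are no-ops.
    """
    w, h = state.width, state.height
    source = (int(rng.integers(w)), int(rng.integers(h)))
    dx, dy = MOORE_OFFSETS[int(rng.integers(8))]
    target = ((source[0] + dx) % w, (source[1] + dy) % h)
    if state.identity[source] == state.identity[target]:
        return False
    dh = delta_h_physical(state, source, target, params)
    dh += delta_h_act(state, source, target, genotype)
    if metropolis_accept(dh, params.temperature, rng):
        apply_copy(state, source, target, genotype)
        return True
    return False


def mcs_step(
    state: LatticeState,
    rng: np.random.Generator,
    params: PhysicalParams,
    genotype: Genotype | None = None,
) -> LatticeState:
    """One Monte Carlo step: width x height copy attempts, then activity decay.

    Every positive activity decreases by 1, floored at 0. The state is
    modified in place and returned.
    """
    for _ in range(state.width * state.height):
        attempt_copy(state, rng, params, genotype)
    np.clip(state.activity - 1.0, 0.0, None, out=state.activity)
    return state
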