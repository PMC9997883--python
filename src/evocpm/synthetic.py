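"""Ground-truth generators for testing the analysis stages.

These produce inputs with known parameters — noiseless Fuerth MSD curves,
exponential autocovariance curves, persistent random walks (PRW) with a
prescribed speed and persistence time, and tiny hand-built lattice states —
so every analysis operation can be validated without running the CPM.

The PRW is an angular-diffusion walk: the heading angle receives Gaussian
increments of variance ``2/P`` per unit time, which makes the step-vector
autocovariance decay as ``exp(-dt/P)`` (the mean of ``cos`` of a Gaussian
of variance ``2 dt / P``), while the step length stays exactly ``s dt``.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .analysis import AutocovCurve, MsdCurve, furth_msd
from .lattice import LatticeState, TCELL
from .migration import Track

__all__ = [
    "PrwSpec",
    "make_furth_msd",
    "make_exp_autocov",
    "make_prw_tracks",
    "make_toy_lattices",
]


@dataclass(frozen=True)
class PrwSpec:
    """Persistent-random-walk ensemble specification."""

    speed: float  # pixels per step
    persistence: float  # steps
    n_steps: int = 2000
    n_tracks: int = 30
    dt: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.speed <= 0 or self.persistence <= 0:
            raise ValueError("speed and persistence must be strictly positive")


def make_furth_msd(
    D: float, P: float, lags: np.ndarray, track_length: int | None = None
) -> MsdCurve:
    """Noiseless Fuerth MSD values at the given lags.

    Weights mimic a single track of ``track_length`` steps via the
    independent-displacement floor rule (defaults to the largest lag).
    """
    if D <= 0 or P <= 0:
        raise ValueError("D and P must be strictly positive")
    lags = np.asarray(lags, dtype=float)
    if track_length is None:
        track_length = int(lags.max())
    positive = lags[lags > 0]
    dt = positive.min() if len(positive) else 1.0
    weights = np.maximum(track_length // np.maximum(lags / dt, 1), 1)
    return MsdCurve(lag=lags, msd=furth_msd(lags, D, P), weight=weights)


def make_exp_autocov(c: float, P: float, lags: np.ndarray) -> AutocovCurve:
    """Noiseless exponential autocovariance ``c * exp(-dt/P)``."""
    if c <= 0 or P <= 0:
        raise ValueError("c and P must be strictly positive")
    lags = np.asarray(lags, dtype=float)
    return AutocovCurve(
        lag=lags, autocov=c * np.exp(-lags / P), n_pairs=np.ones_like(lags)
    )


def make_prw_tracks(spec: PrwSpec) -> list[Track]:
    """Persistent random walks with known speed and persistence time.

    Heading angles follow a Gaussian random walk with per-step variance
    ``2 dt / persistence``; steps have constant length ``speed * dt``.
    """
    rng = np.random.default_rng(spec.seed)
    sigma = np.sqrt(2.0 * spec.dt / spec.persistence)
    tracks = []
    t = np.arange(spec.n_steps + 1) * spec.dt
    for i in range(spec.n_tracks):
        theta = rng.uniform(0, 2 * np.pi) + np.concatenate(
            [[0.0], np.cumsum(rng.normal(0.0, sigma, size=spec.n_steps - 1))]
        )
        step = spec.speed * spec.dt
        x = np.concatenate([[0.0], np.cumsum(step * np.cos(theta))])
        y = np.concatenate([[0.0], np.cumsum(step * np.sin(theta))])
        tracks.append(Track(t=t, x=x, y=y, track_id=i))
    return tracks


def _state_from_rows(rows: list[str], n_cells: int) -> LatticeState:
    ids = np.array([[int(ch) for ch in row] for row in rows], dtype=np.int32)
    kinds = np.zeros(n_cells + 1, dtype=np.int8)
    kinds[1:] = TCELL
    return LatticeState(ids, np.zeros_like(ids, dtype=float), kinds)


def make_toy_lattices() -> dict[str, LatticeState]:
    """Deterministic small lattice fixtures for Hamiltonian and component tests.

    ``single_square``: one 3x3 cell; ``two_touching``: two adjacent cells;
    ``split``: one cell id in two equal disconnected components;
    ``straddling``: one cell crossing the periodic boundary (a single
    component under toroidal adjacency).
    """
    single = _state_from_rows(
        ["00000000", "00111000", "00111000", "00111000", "00000000",
         "00000000", "00000000", "00000000"], 1)
    two = _state_from_rows(
        ["00000000", "01122000", "01122000", "01122000", "00000000",
         "00000000", "00000000", "00000000"], 2)
    split = _state_from_rows(
        ["00000000", "01100000", "01100000", "00000000", "00001100",
         "00001100", "00000000", "00000000"], 1)
    straddle = _state_from_rows(
        ["11000011", "11000011", "00000000", "00000000", "00000000",
         "00000000", "00000000", "00000000"], 1)
    return {
        "single_square": single,
        "two_touching": two,
        "split": split,
        "straddling": straddle,
    }
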