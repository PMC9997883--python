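"""Readers and writers: track CSV, grid snapshots, histories, manifests.

Formats are deliberately plain: tracks and evolution histories are CSV,
lattice snapshots are whitespace-separated integer grids (one row per line),
run manifests are JSON. Everything round-trips at full float precision.
"""
from __future__ import annotations

import json
import time
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .evolution import EvolutionConfig, EvolutionHistory
from .lattice import LatticeState
from .migration import Track

TRACK_COLUMNS = ["track_id", "t", "x", "y"]


def write_tracks(tracks: Track | Sequence[Track], path) -> None:
    """Write tracks as CSV with header ``track_id,t,x,y``."""
    if isinstance(tracks, Track):
        tracks = [tracks]
    frames = [
        pd.DataFrame(
            {"track_id": tr.track_id, "t": tr.t, "x": tr.x, "y": tr.y}
        )
        for tr in tracks
    ]
    df = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=TRACK_COLUMNS)
    )
    df.to_csv(path, index=False, float_format="%.17g")


def read_tracks(path) -> list[Track]:
    """Read a track CSV; rejects malformed rows and non-uniform spacing."""
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ValueError(f"{path}: cannot parse track CSV: {exc}") from exc
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    bad = df[TRACK_COLUMNS[1:]].isna().any(axis=1)
    if bad.any():
        lines = (np.nonzero(bad.to_numpy())[0] + 2).tolist()  # 1-based + header
        raise ValueError(f"{path}: malformed rows at lines {lines[:10]}")
    tracks = []
    for tid, sub in df.groupby("track_id", sort=True):
        try:
            tracks.append(
                Track(
                    t=sub["t"].to_numpy(),
                    x=sub["x"].to_numpy(),
                    y=sub["y"].to_numpy(),
                    track_id=int(tid),
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path}: track {tid}: {exc}") from exc
    return tracks


def write_grid(state: LatticeState, path) -> None:
    """Plain-text snapshot: one grid row of space-separated cell ids per line."""
    np.savetxt(path, state.identity, fmt="%d")


def read_grid(path, cell_kind: np.ndarray | None = None) -> LatticeState:
    ids = np.loadtxt(path, dtype=np.int32)
    if cell_kind is None:
        from .lattice import TCELL

        cell_kind = np.zeros(int(ids.max()) + 1, dtype=np.int8)
        cell_kind[1:] = TCELL
    return LatticeState(ids, np.zeros_like(ids, dtype=float), cell_kind)


HISTORY_COLUMNS = [
    "run", "generation", "individual", "parent",
    "fitness", "broken", "survivor",
]


def write_history(history: EvolutionHistory, path) -> None:
    cols = (
        HISTORY_COLUMNS[:4]
        + list(history.config.param_names)
        + HISTORY_COLUMNS[4:]
    )
    history.table[cols].to_csv(path, index=False, float_format="%.17g")


def read_history(path, config: EvolutionConfig | None = None) -> EvolutionHistory:
    df = pd.read_csv(path)
    if config is None:
        param_names = tuple(c for c in df.columns if c not in HISTORY_COLUMNS)
        config = EvolutionConfig(
            initial_params=tuple(1.0 for _ in param_names),
            param_names=param_names,
            generations=int(df["generation"].max()),
        )
    return EvolutionHistory(table=df, config=config, run=int(df["run"].iloc[0]))


def write_manifest(path, command: str, config: dict, seed: int, outputs: list[str]) -> None:
    """JSON run manifest: command, configuration, master seed, outputs."""
    manifest = {
        "command": command,
        "config": config,
        "seed": int(seed),
        "outputs": outputs,
        "package": "evocpm 0.1.0",
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")


def load_config(path) -> dict:
    """Read a YAML configuration file into a plain dict."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: configuration must be a YAML mapping")
    return cfg
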