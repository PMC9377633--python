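"""Plain-text serialisation: matrices and trajectories as CSV with JSON
metadata sidecars."""

from __future__ import annotations

import json
from dataclasses import asdict, is_dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "save_matrix",
    "load_matrix",
    "trajectory_to_frame",
    "load_trajectory_npz",
    "save_trajectory",
    "save_norms",
]


def _jsonable(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating, np.bool_)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    return obj


def save_matrix(path: str | Path, W: np.ndarray, metadata: dict | None = None) -> None:
    """Write a matrix as CSV; metadata (spec, seed, ...) goes to a
    ``<path>.json`` sidecar."""
    path = Path(path)
    np.savetxt(path, np.asarray(W), delimiter=",")
    if metadata is not None:
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(_jsonable(metadata), indent=2)
        )


def load_matrix(path: str | Path) -> tuple[np.ndarray, dict | None]:
    path = Path(path)
    W = np.loadtxt(path, delimiter=",")
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else None
    return W, meta


def trajectory_to_frame(traj, what: str = "rates") -> pd.DataFrame:
    """Trajectory as a DataFrame: time_ms plus one column per neuron."""
    if what not in ("rates", "states"):
        raise ValueError("what must be 'rates' or 'states'")
    data = getattr(traj, what)
    prefix = "r" if what == "rates" else "x"
    cols = {f"{prefix}_{i + 1}": data[:, i] for i in range(data.shape[1])}
    return pd.DataFrame({"time_ms": traj.times, **cols})


def save_trajectory(path: str | Path, traj, what: str = "rates") -> None:
    """Trajectory as CSV (or as a compact .npz container when the path
    ends in .npz)."""
    path = Path(path)
    if path.suffix == ".npz":
        np.savez_compressed(
            path, times=traj.times, states=traj.states, rates=traj.rates,
            mode=np.array(traj.mode),
        )
        return
    trajectory_to_frame(traj, what).to_csv(path, index=False)


def load_trajectory_npz(path: str | Path):
    from .dynamics import Trajectory

    with np.load(path) as data:
        return Trajectory(
            times=data["times"], states=data["states"], rates=data["rates"],
            mode=str(data["mode"]),
        )


def save_norms(path: str | Path, traj) -> None:
    pd.DataFrame({"time_ms": traj.times, "norm": traj.norms()}).to_csv(
        path, index=False
    )
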