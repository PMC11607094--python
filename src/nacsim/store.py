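"""HDF5 persistence for trajectories and sensitivity results."""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np

from .grid import Grid, ScalarField
from .sensitivity import SAResult
from .solver import Trajectory

__all__ = ["save_trajectory", "load_trajectory", "save_sa_result", "load_sa_result"]


def _write_grid(g: h5py.Group, grid: Grid) -> None:
    g.attrs["shape"] = grid.shape
    g.attrs["spacing"] = grid.spacing
    g.attrs["origin"] = grid.origin


def _read_grid(g: h5py.Group) -> Grid:
    return Grid(tuple(int(v) for v in g.attrs["shape"]),
                tuple(float(v) for v in g.attrs["spacing"]),
                tuple(float(v) for v in g.attrs["origin"]))


def save_trajectory(traj: Trajectory, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("times", data=traj.times)
        f.create_dataset("VT", data=traj.VT)
        f.create_dataset("NT", data=traj.NT)
        f.create_dataset("final", data=traj.final.values)
        _write_grid(f, traj.final.grid)
        snaps = f.create_group("snapshots")
        for t, fld in traj.snapshots.items():
            snaps.create_dataset(f"{t:g}", data=fld.values)


def load_trajectory(path: str | Path) -> Trajectory:
    with h5py.File(path, "r") as f:
        grid = _read_grid(f)
        snaps = {
            float(k): ScalarField(grid, np.asarray(v))
            for k, v in f["snapshots"].items()
        }
        return Trajectory(
            times=np.asarray(f["times"]), VT=np.asarray(f["VT"]),
            NT=np.asarray(f["NT"]), snapshots=snaps,
            final=ScalarField(grid, np.asarray(f["final"])),
        )


def save_sa_result(res: SAResult, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["regimen_kind"] = res.regimen_kind
        f.attrs["eps_s"] = res.eps_s
        f.attrs["param_names"] = list(res.param_names)
        if res.seed is not None:
            f.attrs["seed"] = res.seed
        for name in ("times", "ST", "ci_lo", "ci_hi", "influential",
                     "YA", "YB", "YAB", "A", "B", "final_A", "final_B"):
            f.create_dataset(name, data=getattr(res, name))


def load_sa_result(path: str | Path) -> SAResult:
    with h5py.File(path, "r") as f:
        kw = {name: np.asarray(f[name])
              for name in ("times", "ST", "ci_lo", "ci_hi", "YA", "YB",
                           "YAB", "A", "B", "final_A", "final_B")}
        return SAResult(
            regimen_kind=str(f.attrs["regimen_kind"]),
            param_names=tuple(str(n) for n in f.attrs["param_names"]),
            eps_s=float(f.attrs["eps_s"]),
            influential=np.asarray(f["influential"]).astype(bool),
            seed=int(f.attrs["seed"]) if "seed" in f.attrs else None,
            **kw,
        )
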