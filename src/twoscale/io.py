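"""Configuration loading, validation and result serialisation.

Runs are described by a small YAML configuration with sections ``grid``,
``mhb``, ``integration``, ``ic``, ``mirna``, ``fit`` and ``filter``; every
stochastic command requires an explicit seed.  Results are written as
delimited tables (one per species for trajectories, one per steady state for
attractor catalogues) plus a JSON provenance record holding the resolved
configuration, package version, seeds and wall time.
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .grn import HillParams
from .mhb import MHBParams
from .mirna import MiRNAParams
from .pde import Grid, Trajectory

__all__ = [
    "default_config",
    "load_config",
    "resolve",
    "export_trajectory",
    "export_state",
    "import_state",
    "write_provenance",
]


def default_config() -> dict:
    """Configuration reproducing the reference two-steady-state setup."""
    return {
        "grid": {"L": 2.0, "N": 250},
        "mhb": {
            "alpha": [1.0] * 8,
            "beta": [1.0] * 8,
            "k": 0.1,
            "n": 2.0,
            "d_fgf8": 0.001,
            "d_wnt1": 0.001,
        },
        "integration": {"rtol": 1e-8, "atol": 1e-10, "t_final": 50.0},
        "steady": {
            "check_interval": 1.0,
            "tol": 1e-10,
            "t_max": 200.0,
            "n_samples": 24,
            "dedup_tol": 0.1,
            "seed": 1,
        },
        "ic": {"kind": "unimodal", "xstar": 0.0, "widths": 0.18, "amplitudes": 0.7},
        "mirna": {
            "scenario": "ii",
            "p1": 0.1,
            "p2": 0.3,
            "p4": 1.0,
            "beta_m": 0.1,
            "d_m": 0.0,
            "kappa": 20.0,
            "lam": 1.0,
            "l_values": [round(0.1 * i, 1) for i in range(11)],
        },
        "fit": {"init": [0.1, 0.3, 1.0, 0.5], "reference_means": [1.0]},
        "filter": {"min_tools": 3, "min_off": 2},
    }


def load_config(path) -> dict:
    """Load a YAML config, layering it over the defaults."""
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    cfg = default_config()
    for section, values in user.items():
        if section not in cfg:
            raise ValueError(f"unknown config section {section!r}")
        if isinstance(values, dict):
            cfg[section] = {**cfg[section], **values}
        else:
            cfg[section] = values
    return cfg


def resolve(cfg: dict):
    """Build (Grid, MHBParams, MiRNAParams) from a configuration dict."""
    g = cfg["grid"]
    grid = Grid(L=float(g["L"]), N=int(g["N"]))
    m = cfg["mhb"]
    mhb = MHBParams(
        alpha=tuple(float(a) for a in m["alpha"]),
        beta=tuple(float(b) for b in m["beta"]),
        hill=HillParams(k=float(m["k"]), n=float(m["n"])),
        d_fgf8=float(m["d_fgf8"]),
        d_wnt1=float(m["d_wnt1"]),
    )
    mi = cfg["mirna"]
    mirna = MiRNAParams(
        p1=float(mi["p1"]),
        p2=float(mi["p2"]),
        p4=float(mi["p4"]),
        l=float(mi.get("l", 0.45)),
        beta_m=float(mi["beta_m"]),
        d_m=float(mi["d_m"]),
        kappa=float(mi["kappa"]),
        lam=float(mi["lam"]),
    )
    return grid, mhb, mirna


def export_state(state: np.ndarray, species, grid: Grid, path) -> None:
    """Write a field state as one delimited table (rows species, cols nodes)."""
    df = pd.DataFrame(state, index=list(species), columns=np.round(grid.x, 10))
    df.index.name = "species"
    df.to_csv(path)


def import_state(path) -> np.ndarray:
    """Read a field state previously written by :func:`export_state`."""
    df = pd.read_csv(path, index_col=0)
    return df.to_numpy(dtype=float)


def export_trajectory(traj: Trajectory, outdir) -> list[Path]:
    """One table per species: rows = times, columns = node positions."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    cols = np.round(traj.grid.x, 10)
    for j, name in enumerate(traj.species):
        df = pd.DataFrame(traj.states[:, j, :], index=traj.times, columns=cols)
        df.index.name = "time"
        p = outdir / f"trajectory_{name}.csv"
        df.to_csv(p)
        written.append(p)
    return written


def write_provenance(outdir, cfg: dict, command: str, t_start: float, extra=None) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    record = {
        "command": command,
        "package_version": __version__,
        "config": cfg,
        "wall_time_s": round(time.time() - t_start, 3),
    }
    if extra:
        record.update(extra)
    p = outdir / "provenance.json"
    with open(p, "w") as fh:
        json.dump(record, fh, indent=2, default=float)
    return p
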