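"""Configuration, serialization and reproducibility plumbing.

Configs are TOML files with ``[simulation]`` and ``[metrics]`` sections
mirroring :class:`~ecmflock.params.SimulationParams` and
:class:`~ecmflock.metrics.MetricConfig`; a top-level ``preset`` key starts
from a named tissue preset.  Simulation state round-trips exactly through
``save_state``/``load_state`` (cell arrays, fiber grid, RNG stream position),
which is what the two-phase remodeling workflow relies on.  Fiber grids also
serialize to a plain-text dense-array format.
"""

from __future__ import annotations

import json
import platform
import time
import tomllib
from dataclasses import fields as dc_fields
from pathlib import Path

import numpy as np

from . import __version__
from .fiber_grid import FiberGrid
from .metrics import MetricConfig
from .model import Simulation
from .params import SimulationParams, TISSUE_PRESETS

__all__ = [
    "load_config",
    "save_state",
    "load_state",
    "save_grid",
    "load_grid",
    "write_manifest",
]

_STATE_VERSION = 1


def load_config(path) -> dict:
    """Parse a TOML config into validated parameter objects.

    Returns ``{"simulation": SimulationParams, "metrics": MetricConfig}``.
    Unknown keys raise with a listing; so do invalid weight combinations.
    """
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    sim_kwargs = dict(raw.pop("simulation", {}))
    preset = raw.pop("preset", None)
    metric_kwargs = dict(raw.pop("metrics", {}))
    if raw:
        raise ValueError(f"unknown config sections/keys: {sorted(raw)}")
    if preset is not None:
        if preset not in TISSUE_PRESETS:
            raise ValueError(
                f"unknown preset {preset!r}; choose from {sorted(TISSUE_PRESETS)}")
        base = TISSUE_PRESETS[preset].to_dict()
        base.update(sim_kwargs)
        sim_kwargs = base
    params = SimulationParams.from_dict(sim_kwargs)
    known_metric = {f.name for f in dc_fields(MetricConfig)}
    unknown = set(metric_kwargs) - known_metric
    if unknown:
        raise ValueError(f"unknown metrics keys: {sorted(unknown)}")
    return {"simulation": params, "metrics": MetricConfig(**metric_kwargs)}


def save_state(sim: Simulation, path) -> None:
    """Serialize a full simulation state (exact round-trip, incl. RNG)."""
    np.savez(
        path,
        version=_STATE_VERSION,
        theta=sim.theta,
        speed=sim.speed,
        pos=sim.pos,
        pos_unwrapped=sim.pos_unwrapped,
        grid_bins=sim.grid.bins,
        t=sim.t,
        params_json=json.dumps(sim.params.to_dict()),
        rng_state_json=json.dumps(sim.rng.bit_generator.state),
        noise_rng_state_json=json.dumps(sim._noise_rng.bit_generator.state),
        select_rng_state_json=json.dumps(sim._select_rng.bit_generator.state),
    )


def load_state(path) -> Simulation:
    """Restore a simulation saved with :func:`save_state`."""
    with np.load(path, allow_pickle=False) as data:
        version = int(data["version"])
        if version != _STATE_VERSION:
            raise ValueError(f"state version {version} != supported {_STATE_VERSION}")
        params = SimulationParams.from_dict(json.loads(str(data["params_json"])))
        sim = Simulation(params, np.random.default_rng(0))
        for attr, key in (("rng", "rng_state_json"),
                          ("_noise_rng", "noise_rng_state_json"),
                          ("_select_rng", "select_rng_state_json")):
            gen = np.random.default_rng()
            gen.bit_generator.state = json.loads(str(data[key]))
            setattr(sim, attr, gen)
        sim.theta = data["theta"].copy()
        sim.speed = data["speed"].copy()
        sim.pos = data["pos"].copy()
        sim.pos_unwrapped = data["pos_unwrapped"].copy()
        sim.grid.bins = data["grid_bins"].copy()
        sim.t = int(data["t"])
    return sim


def save_grid(grid: FiberGrid, path) -> None:
    """Write a fiber grid as plain text: metadata header + dense bin matrix.

    Rows are grid points in x-fastest order; columns the bin counts.
    """
    header = (f"nx={grid.nx} ny={grid.ny} width={grid.width} "
              f"height={grid.height} n_bins={grid.n_bins}")
    dense = grid.bins.transpose(1, 0, 2).reshape(grid.nx * grid.ny, grid.n_bins)
    np.savetxt(path, dense, header=header, delimiter=",")


def load_grid(path) -> FiberGrid:
    with open(path) as fh:
        meta = dict(kv.split("=") for kv in fh.readline().lstrip("# ").split())
    nx, ny, nb = int(meta["nx"]), int(meta["ny"]), int(meta["n_bins"])
    grid = FiberGrid((nx, ny), (float(meta["width"]), float(meta["height"])), nb)
    dense = np.loadtxt(path, delimiter=",", skiprows=1).reshape(ny, nx, nb)
    grid.bins = dense.transpose(1, 0, 2).copy()
    return grid


def write_manifest(out_dir, config_snapshot: dict, seed, files, started: float) -> Path:
    """Write a run manifest naming every output file (atomic rename)."""
    out_dir = Path(out_dir)
    manifest = {
        "software": f"ecmflock {__version__}",
        "python": platform.python_version(),
        "seed": seed,
        "config": config_snapshot,
        "files": [str(f) for f in files],
        "wall_clock_s": round(time.time() - started, 3),
    }
    tmp = out_dir / "manifest.json.tmp"
    tmp.write_text(json.dumps(manifest, indent=2, default=str))
    final = out_dir / "manifest.json"
    tmp.rename(final)
    return final
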