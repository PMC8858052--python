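"""File I/O: configs (YAML/JSON), trajectories (CSV + JSON sidecar), manifests.

Numbers are serialized at full precision (``repr`` round-trip), so a
write/read cycle reproduces every field bitwise.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .config import RunConfig, config_from_dict, config_to_dict
from .model import STATE_NAMES
from .solver import Trajectory

__all__ = [
    "read_config",
    "write_config",
    "write_trajectory",
    "read_trajectory",
    "write_manifest",
]

TRAJECTORY_COLUMNS = ("t",) + STATE_NAMES


def read_config(path) -> RunConfig:
    """Load and validate a YAML or JSON run configuration."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} does not contain a key-value mapping")
    return config_from_dict(data)


def write_config(config: RunConfig, path) -> Path:
    """Write a config as flat key-value YAML (or JSON by extension)."""
    path = Path(path)
    data = config_to_dict(config)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))
    return path


def write_trajectory(trajectory: Trajectory, path) -> Path:
    """Write a trajectory as CSV with a ``.meta.json`` sidecar.

    Columns are fixed as ``t, C_A, C_B, C_C, C_D, C_E``; the sidecar
    carries the scheme, theta, step, parameter fingerprint and package
    version.
    """
    path = Path(path)
    df = trajectory.to_dataframe()
    df.to_csv(path, index=False, float_format="%.17g")
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    meta = dict(trajectory.meta)
    meta["version"] = __version__
    sidecar.write_text(json.dumps(meta, indent=2, default=float) + "\n")
    return path


def read_trajectory(path) -> Trajectory:
    """Read a trajectory CSV (and its sidecar, if present) back."""
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if tuple(df.columns) != TRAJECTORY_COLUMNS:
        raise ValueError(
            f"trajectory file must have columns {TRAJECTORY_COLUMNS}, got {tuple(df.columns)}"
        )
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return Trajectory(
        grid=df["t"].to_numpy(),
        states=df[list(STATE_NAMES)].to_numpy(),
        meta=meta,
    )


def write_manifest(config: RunConfig, outdir, extra: dict | None = None) -> Path:
    """Write a reproducibility manifest: full config + code version.

    Re-running from the manifest reproduces the outputs bitwise (the
    pipeline is deterministic).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": config_to_dict(config),
        "version": __version__,
        "note": "parameter values are assumed (no baseline is printed in the source study)",
    }
    if extra:
        manifest.update(extra)
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=float) + "\n")
    return path
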