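"""Configuration files, trajectory tables, and run manifests.

Configs are YAML mirroring :class:`~mitoq.integrator.SimulationConfig`
field names; trajectories are plain CSV in tidy layout at full float
precision, so the 12-decimal probability-conservation criterion is
auditable straight from the files.  A JSON run manifest (scenario name,
fully resolved parameters, seed, software version, timestamps) plus the
seed suffices to reproduce any run bit-identically.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from .core import ModelParameters, ProcessTimeLaw
from .integrator import SimulationConfig, Trajectory

__all__ = [
    "ConfigError",
    "config_to_dict",
    "config_from_dict",
    "read_config",
    "write_config",
    "write_trajectory",
    "read_metrics",
    "RunManifest",
    "write_manifest",
]

_LAW_KEYS = ("ffm", "ffp_fusion", "ffp_fission", "mb", "rep", "ec", "ed")


class ConfigError(ValueError):
    """Malformed or inconsistent configuration file."""


def _law_to_dict(law: ProcessTimeLaw) -> dict:
    return {"rho0": law.rho0, "tau": law.tau, "direction": law.direction.value,
            "cap": law.cap}


def config_to_dict(config: SimulationConfig) -> dict:
    """Plain nested-dict form of a config (YAML/JSON-ready)."""
    p = config.params
    return {
        "Q": config.Q,
        "dt": config.dt,
        "n_steps": config.n_steps,
        "initial": config.initial if isinstance(config.initial, str) else list(config.initial),
        "enabled": list(config.enabled),
        "seed": config.seed,
        "record_every": config.record_every,
        "record_snapshots": config.record_snapshots,
        "params": {
            "gamma": p.gamma,
            "ff1": p.ff1,
            "ff2": p.ff2,
            "f_rd": p.f_rd,
            "laws": {key: _law_to_dict(getattr(p, f"law_{key}")) for key in _LAW_KEYS},
        },
    }


def config_from_dict(tree: dict) -> SimulationConfig:
    """Rebuild a :class:`SimulationConfig` from its nested-dict form."""
    try:
        ptree = tree["params"]
        laws = {
            f"law_{key}": ProcessTimeLaw(
                rho0=float(ptree["laws"][key]["rho0"]),
                tau=float(ptree["laws"][key]["tau"]),
                direction=ptree["laws"][key]["direction"],
                cap=bool(ptree["laws"][key].get("cap", False)),
            )
            for key in _LAW_KEYS
        }
        params = ModelParameters(
            gamma=float(ptree["gamma"]),
            ff1=float(ptree["ff1"]),
            ff2=float(ptree["ff2"]),
            f_rd=float(ptree["f_rd"]),
            **laws,
        )
        return SimulationConfig(
            params=params,
            Q=int(tree["Q"]),
            dt=float(tree["dt"]),
            n_steps=int(tree["n_steps"]),
            initial=tree["initial"],
            enabled=tuple(tree["enabled"]),
            seed=int(tree["seed"]),
            record_every=int(tree["record_every"]),
            record_snapshots=bool(tree.get("record_snapshots", False)),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigError(f"invalid configuration: {exc}") from exc


def read_config(path) -> SimulationConfig:
    """Load a YAML config file; raises :class:`ConfigError` if malformed."""
    text = Path(path).read_text()
    try:
        tree = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(tree, dict):
        raise ConfigError(f"{path} does not contain a configuration mapping")
    return config_from_dict(tree)


def write_config(config: SimulationConfig, path) -> None:
    """Write a config as YAML (floats round-trip at full precision)."""
    Path(path).write_text(
        yaml.safe_dump(config_to_dict(config), sort_keys=False, default_flow_style=False)
    )


def write_trajectory(traj: Trajectory, outdir) -> dict:
    """Write ``metrics.csv`` (t, qbar, sigma_q, p0, nprob) and, if recorded,
    ``snapshots.csv`` (t, q, P) under ``outdir``; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"metrics": outdir / "metrics.csv"}
    traj.metrics.to_csv(paths["metrics"], index=False, float_format="%.17g")
    if traj.snapshots is not None:
        rows = [
            {"t": t, "q": q, "P": p_q}
            for t, vec in traj.snapshots
            for q, p_q in enumerate(vec)
        ]
        paths["snapshots"] = outdir / "snapshots.csv"
        pd.DataFrame(rows, columns=["t", "q", "P"]).to_csv(
            paths["snapshots"], index=False, float_format="%.17g"
        )
    return paths


def read_metrics(path) -> pd.DataFrame:
    """Load a metrics CSV written by :func:`write_trajectory`."""
    return pd.read_csv(path, dtype=float, float_precision="round_trip")


@dataclass
class RunManifest:
    """Provenance record for one simulation run."""

    scenario: Optional[str]
    config: dict
    seed: int
    version: str
    created: str = field(default_factory=lambda: _dt.datetime.now(_dt.timezone.utc).isoformat())
    finished: Optional[str] = None
    nprob_final: Optional[float] = None
    normalization_ok: Optional[bool] = None


def write_manifest(manifest: RunManifest, outdir) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / "manifest.json"
    path.write_text(json.dumps(asdict(manifest), indent=2) + "\n")
    return path
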