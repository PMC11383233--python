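"""Run configuration (TOML) and output writers.

A RunConfig bundles the model parameters with integration and analysis
settings.  Loading validates exhaustively (all schema violations are
reported at once) and fills defaults; every output embeds a hash of the
fully resolved configuration for provenance.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import tomllib
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .params import ModelParameters
from .simulate import BurstSummary, Trajectory


class ConfigError(ValueError):
    """Carries the full list of validation problems."""

    def __init__(self, problems):
        self.problems = list(problems)
        super().__init__("invalid configuration:\n  - " +
                         "\n  - ".join(self.problems))


@dataclass(frozen=True)
class IntegrationConfig:
    dt: float = 0.005               # ms
    t_end: float = 12000.0          # ms
    transient_discard: float = 2000.0
    record_stride: int = 4
    method: str = "rk4"             # rk4 | rk45


@dataclass(frozen=True)
class AnalysisConfig:
    spike_threshold: float = 0.0    # mV, upward crossing
    refractory: float = 2.0         # ms
    rest_ceiling: float = -60.0     # mV
    block_floor: float = -50.0      # mV
    tail_window: float = 2000.0     # ms
    isi_gap_ratio: float = 3.0      # bimodality criterion


@dataclass(frozen=True)
class OutputConfig:
    directory: str = "."
    format: str = "csv"


@dataclass(frozen=True)
class RunConfig:
    model: ModelParameters = field(default_factory=ModelParameters)
    integration: IntegrationConfig = field(default_factory=IntegrationConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    output: OutputConfig = field(default_factory=OutputConfig)

    def to_dict(self) -> dict:
        return {
            "model": self.model.to_dict(),
            "integration": dataclasses.asdict(self.integration),
            "analysis": dataclasses.asdict(self.analysis),
            "output": dataclasses.asdict(self.output),
        }

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def replace_model(self, **kwargs) -> "RunConfig":
        return dataclasses.replace(self, model=self.model.replace(**kwargs))


_SECTIONS = {
    "model": ModelParameters,
    "integration": IntegrationConfig,
    "analysis": AnalysisConfig,
    "output": OutputConfig,
}


def _build_section(cls, data: dict, section: str, problems: list):
    known = {f.name: f for f in fields(cls)}
    kwargs = {}
    for key, value in data.items():
        if key not in known:
            problems.append(f"[{section}] unknown key: {key!r}")
            continue
        kwargs[key] = value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as e:
        problems.append(f"[{section}] {e}")
        return cls()


def load_config(path) -> RunConfig:
    """Load and validate a TOML run configuration; defaults fill gaps.

    Unknown sections or keys and invalid values are collected and reported
    together in a single ConfigError.
    """
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    problems: list = []
    sections = {}
    for name, payload in data.items():
        if name not in _SECTIONS:
            problems.append(f"unknown section: [{name}]")
            continue
        if not isinstance(payload, dict):
            problems.append(f"section [{name}] must be a table")
            continue
        sections[name] = payload
    cfg = RunConfig(**{
        name: _build_section(cls, sections.get(name, {}), name, problems)
        for name, cls in _SECTIONS.items()
    })
    if problems:
        raise ConfigError(problems)
    return cfg


def write_config_echo(cfg: RunConfig, out_dir) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "resolved_config.json"
    payload = cfg.to_dict()
    payload["config_hash"] = cfg.config_hash()
    path.write_text(json.dumps(payload, indent=2))
    return path


def trajectory_to_csv(traj: Trajectory, path, cfg: Optional[RunConfig] = None) -> Path:
    """Write a trajectory as CSV (t_ms, V_mV, h, n, Kout_mM[, Nain_mM])."""
    path = Path(path)
    cols = {"t_ms": traj.times, "V_mV": traj.V, "h": traj.h, "n": traj.n}
    if traj.K_out is not None:
        cols["Kout_mM"] = traj.K_out
    if traj.Na_in is not None:
        cols["Nain_mM"] = traj.Na_in
    header = ""
    if cfg is not None:
        header = f"# config_hash={cfg.config_hash()}\n"
    with open(path, "w") as fh:
        fh.write(header)
        pd.DataFrame(cols).to_csv(fh, index=False, float_format="%.17g")
    return path


def trajectory_from_csv(path, params: Optional[ModelParameters] = None) -> Trajectory:
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    return Trajectory(
        df["t_ms"].to_numpy(), df["V_mV"].to_numpy(), df["h"].to_numpy(),
        df["n"].to_numpy(),
        df["Kout_mM"].to_numpy() if "Kout_mM" in df else None,
        df["Nain_mM"].to_numpy() if "Nain_mM" in df else None,
        params or ModelParameters(), {"source": str(path)})


def burst_summary_to_json(summary: BurstSummary, path,
                          cfg: Optional[RunConfig] = None) -> Path:
    path = Path(path)
    payload = {
        "regime": summary.regime,
        "spikes_per_burst": list(summary.spikes_per_burst),
        "modal_spikes_per_burst": summary.modal_spikes_per_burst,
        "interburst_period_ms": _num(summary.interburst_period),
        "interburst_interval_ms": _num(summary.interburst_interval),
        "intra_burst_isi_mean_ms": _num(summary.intra_burst_isi_mean),
        "Kout_min_mM": _num(summary.K_out_min),
        "Kout_max_mM": _num(summary.K_out_max),
        "period_doubled": summary.period_doubled,
        "n_bursts": summary.n_bursts,
    }
    if cfg is not None:
        payload["config_hash"] = cfg.config_hash()
    path.write_text(json.dumps(payload, indent=2))
    return path


def _num(x):
    return None if x is None or not np.isfinite(x) else float(x)


def preflight_writable(path) -> None:
    """Fail before computation if the output location is not writable."""
    path = Path(path)
    parent = path if path.is_dir() else path.parent
    probe = parent / f".pumpburst_write_probe_{id(path)}"
    try:
        parent.mkdir(parents=True, exist_ok=True)
        probe.write_text("")
        probe.unlink()
    except OSError as e:
        raise OSError(f"output path {path} is not writable: {e}") from e
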