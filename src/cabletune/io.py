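"""Configuration files, result serialization and run manifests.

The configuration is a YAML mapping with up to three sections —
``substrate``, ``protocol`` and ``ga`` — whose keys are exactly the
fields of :class:`~cabletune.substrate.SubstrateConfig`,
:class:`~cabletune.experiment.ProtocolConfig` and
:class:`~cabletune.evolution.GAConfig`.  Unspecified keys take the
documented defaults; unknown keys are an error.  All results are written
as CSV (tables) and JSON (nested metadata); every command additionally
writes a run manifest listing the exact config, the seed streams and a
SHA-256 hash of each output file, which is sufficient to re-run the
command bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, fields
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .evolution import GAConfig, GAResult
from .experiment import AmplitudeMatrix, Observation, ProtocolConfig
from .landscape import GridResult
from .substrate import RecordingSet, SubstrateConfig

__all__ = [
    "ConfigError",
    "RunConfig",
    "load_config",
    "dump_config",
    "RunManifest",
    "write_manifest",
    "recording_to_csv",
    "observation_to_json",
    "amplitude_matrix_to_csv",
    "grid_to_csv",
    "history_to_csv",
]


class ConfigError(ValueError):
    """Malformed configuration file."""


@dataclass(frozen=True)
class RunConfig:
    substrate: SubstrateConfig
    protocol: ProtocolConfig
    ga: GAConfig


_SECTIONS = {
    "substrate": SubstrateConfig,
    "protocol": ProtocolConfig,
    "ga": GAConfig,
}

_TUPLE_FIELDS = {"g_l_range", "g_ic_range", "adc_range"}


def _build_section(name: str, cls, data: dict):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(
            f"unknown key(s) in section '{name}': {', '.join(sorted(unknown))}"
        )
    kwargs = {}
    for key, value in data.items():
        if key in _TUPLE_FIELDS:
            if not isinstance(value, (list, tuple)) or len(value) != 2:
                raise ConfigError(f"'{name}.{key}' must be a pair [min, max]")
            value = (float(value[0]), float(value[1]))
        kwargs[key] = value
    try:
        return cls(**kwargs)
    except ValueError as exc:
        raise ConfigError(f"invalid value in section '{name}': {exc}") from exc


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load and validate a YAML config; a missing path or empty file
    yields the full default configuration."""
    data: dict = {}
    if path is not None:
        text = Path(path).read_text()
        parsed = yaml.safe_load(text)
        if parsed is None:
            parsed = {}
        if not isinstance(parsed, dict):
            raise ConfigError("config file must contain a mapping")
        data = parsed
    unknown = set(data) - set(_SECTIONS)
    if unknown:
        raise ConfigError(f"unknown section(s): {', '.join(sorted(unknown))}")
    sections = {
        name: _build_section(name, cls, data.get(name, {}) or {})
        for name, cls in _SECTIONS.items()
    }
    return RunConfig(**sections)


def dump_config(cfg: RunConfig) -> dict:
    """Normalized plain-dict form of a configuration (round-trips through
    load_config after YAML serialization)."""
    out = {}
    for name in _SECTIONS:
        section = dataclasses.asdict(getattr(cfg, name))
        for key, value in section.items():
            if isinstance(value, tuple):
                section[key] = list(value)
        out[name] = section
    return out


# --------------------------------------------------------------------------
# run manifests
# --------------------------------------------------------------------------


@dataclass
class RunManifest:
    command: str
    config: dict
    master_seed: int | None
    outputs: dict  # filename -> sha256
    version: str
    timestamp: str


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_manifest(
    out_dir: str | Path,
    command: str,
    cfg: RunConfig,
    seed: int | None,
    outputs: list[str | Path],
) -> Path:
    from . import __version__

    out_dir = Path(out_dir)
    manifest = RunManifest(
        command=command,
        config=dump_config(cfg),
        master_seed=seed,
        outputs={Path(p).name: _sha256(Path(p)) for p in outputs},
        version=__version__,
        timestamp=datetime.now(timezone.utc).isoformat(),
    )
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(dataclasses.asdict(manifest), indent=2) + "\n")
    return path


# --------------------------------------------------------------------------
# result serialization
# --------------------------------------------------------------------------


def recording_to_csv(rec: RecordingSet, path: str | Path) -> None:
    """One column per compartment of integer ADC codes, with a JSON
    metadata sidecar carrying dt and the seed."""
    path = Path(path)
    frame = pd.DataFrame(
        rec.traces.T,
        columns=[f"compartment_{i}" for i in range(rec.n_compartments)],
    )
    frame.insert(0, "time", np.arange(rec.n_samples) * rec.dt)
    frame.to_csv(path, index=False)
    sidecar = {"dt": rec.dt, **{k: v for k, v in rec.meta.items()}}
    path.with_suffix(".meta.json").write_text(json.dumps(sidecar, indent=2) + "\n")


def observation_to_json(obs: Observation, path: str | Path) -> None:
    payload = {
        "amplitudes_bits": [float(a) for a in obs.amplitudes],
        "lambda_emp": obs.lambda_emp,
        "h0_bits": obs.h0,
        "fit": dataclasses.asdict(obs.fit),
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def amplitude_matrix_to_csv(mat: AmplitudeMatrix, path: str | Path) -> None:
    n = mat.h.shape[0]
    frame = pd.DataFrame(
        mat.h,
        index=[f"recorded_{i}" for i in range(n)],
        columns=[f"input_{j}" for j in range(n)],
    )
    frame.to_csv(path)


def grid_to_csv(grid: GridResult, prefix: str | Path) -> list[Path]:
    """Write lambda and h0 maps as CSV matrices (axis headers included)
    plus a JSON sidecar with failed cells."""
    prefix = Path(prefix)
    written = []
    for name, data in (("lambda", grid.lambda_map), ("h0", grid.h0_map)):
        frame = pd.DataFrame(
            data,
            index=pd.Index(grid.gl_axis, name="dac_gl"),
            columns=pd.Index(grid.gic_axis, name="dac_gic"),
        )
        p = prefix.with_name(prefix.name + f"_{name}.csv")
        frame.to_csv(p)
        written.append(p)
    meta = {
        "failed_cells": [list(c) for c in grid.failed_cells],
        **{k: v for k, v in grid.meta.items()},
    }
    p = prefix.with_name(prefix.name + "_meta.json")
    p.write_text(json.dumps(meta, indent=2) + "\n")
    written.append(p)
    return written


def history_to_csv(result: GAResult, path: str | Path) -> None:
    """Tidy per-generation GA history: one row per individual."""
    rows = []
    for rec in result.records:
        for i, (genes, fit) in enumerate(zip(rec.genes, rec.fitnesses)):
            rows.append(
                {
                    "generation": rec.generation,
                    "individual": i,
                    "fitness": fit,
                    "is_best": i == rec.best_index,
                    **{f"gene_{k}": int(g) for k, g in enumerate(genes)},
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def ga_summary_json(result: GAResult, path: str | Path) -> None:
    payload = {
        "best_genes": [int(g) for g in result.best.genes],
        "best_fitness": result.best.fitness,
        "n_generations_run": result.n_generations_run,
        "per_generation": [
            {
                "generation": r.generation,
                "best_fitness": r.best_fitness,
                "mean_fitness": r.mean_fitness,
                "best_genes": [int(g) for g in r.best_genes],
            }
            for r in result.records
        ],
        "config": dataclasses.asdict(result.config),
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
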