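"""Structured run configuration for the CLI.

A single YAML file holds one block per pipeline stage; command-line flags
override file values. Unknown keys anywhere are rejected with an error
naming the offending field.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import yaml

from .errors import ConfigError
from .simulate import SimConfig, rna002_config, rna004_config

__all__ = ["RunConfig", "load_run_config", "build_sim_config", "config_hash"]

_SIM_FIELDS = {f.name for f in dataclasses.fields(SimConfig)}
_TOP_KEYS = {"seed", "out_dir", "simulate", "segment", "evaluate", "diagnose"}
_SIMULATE_KEYS = _SIM_FIELDS | {"n_reads", "preset"}
_SEGMENT_KEYS = {"methods"}
_EVALUATE_KEYS = {"window_n", "statistic", "bootstrap_B", "bandwidth"}
_DIAGNOSE_KEYS = {"tail_cutoff", "max_gap_seconds", "run_threshold",
                  "content_threshold", "end_threshold_nt"}


@dataclasses.dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "tailbench_out"
    simulate: dict = dataclasses.field(default_factory=dict)
    segment: dict = dataclasses.field(default_factory=dict)
    evaluate: dict = dataclasses.field(default_factory=dict)
    diagnose: dict = dataclasses.field(default_factory=dict)


def _check_keys(block: dict, allowed: set[str], where: str) -> None:
    for key in block:
        if key not in allowed:
            raise ConfigError(f"{where}.{key}", "unknown configuration key")


def load_run_config(path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(str(path), "config file must be a mapping")
    _check_keys(raw, _TOP_KEYS, "config")
    cfg = RunConfig()
    cfg.seed = int(raw.get("seed", cfg.seed))
    cfg.out_dir = str(raw.get("out_dir", cfg.out_dir))
    for name, allowed in (("simulate", _SIMULATE_KEYS),
                          ("segment", _SEGMENT_KEYS),
                          ("evaluate", _EVALUATE_KEYS),
                          ("diagnose", _DIAGNOSE_KEYS)):
        block = raw.get(name, {}) or {}
        if not isinstance(block, dict):
            raise ConfigError(f"config.{name}", "must be a mapping")
        _check_keys(block, allowed, name)
        setattr(cfg, name, block)
    return cfg


def build_sim_config(block: dict) -> SimConfig:
    """SimConfig from the ``simulate`` block (preset plus field overrides)."""
    block = dict(block)
    block.pop("n_reads", None)
    preset = block.pop("preset", "rna002")
    if preset == "rna002":
        base = rna002_config()
    elif preset == "rna004":
        base = rna004_config()
    else:
        raise ConfigError("simulate.preset", f"unknown preset {preset!r}")
    for key in block:
        if key not in _SIM_FIELDS:
            raise ConfigError(f"simulate.{key}", "unknown configuration key")
    cfg = dataclasses.replace(base, **block)
    cfg.validate()
    return cfg


def config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(dataclasses.asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]
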