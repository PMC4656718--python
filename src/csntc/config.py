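"""Configuration tree: every tunable default in one place, loadable from
YAML/JSON so experiments are reproducible from a single file.

The tree mirrors the package's parameter dataclasses::

    protocol:   experiments.Protocol
    reservoir:  cortex.ReservoirSpec      (single-module experiments)
    bg:         basal_ganglia.BGParams    (+ nested layer: LayerParams)
    wiring:     module.ModuleWiring
    system:     system.SystemSpec         (+ nested oja: OjaConfig)
    bpdc:       learning.BPDCConfig
    arm:        plant.ArmModel

``load_config`` reads a file and merges it over the defaults, so a config
file only needs the fields it changes.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import yaml

from .basal_ganglia import BGParams
from .cortex import ReservoirSpec
from .dynamics import LayerParams
from .experiments import Protocol
from .learning import BPDCConfig, OjaConfig
from .module import ModuleWiring
from .plant import ArmModel
from .system import SystemSpec

__all__ = ["default_config", "load_config", "build"]


def default_config() -> dict:
    """The full default parameter tree as nested plain dicts."""
    return {
        "protocol": dataclasses.asdict(Protocol()),
        "reservoir": dataclasses.asdict(ReservoirSpec()),
        "bg": dataclasses.asdict(BGParams()),
        "wiring": dataclasses.asdict(ModuleWiring()),
        "system": dataclasses.asdict(SystemSpec()),
        "bpdc": dataclasses.asdict(BPDCConfig()),
        "arm": dataclasses.asdict(ArmModel()),
    }


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for key, val in override.items():
        if key in out and isinstance(out[key], dict) and isinstance(val, dict):
            out[key] = _merge(out[key], val)
        else:
            out[key] = val
    return out


def load_config(path: str | Path | None = None) -> dict:
    """Defaults merged with the YAML/JSON file at ``path`` (if given)."""
    cfg = default_config()
    if path is None:
        return cfg
    text = Path(path).read_text()
    data = (json.loads(text) if str(path).endswith(".json")
            else yaml.safe_load(text)) or {}
    return _merge(cfg, data)


def _tupleize(value):
    return tuple(tuple(v) if isinstance(v, (list, tuple)) else v
                 for v in value) if isinstance(value, (list, tuple)) else value


def build(cfg: dict):
    """Instantiate the parameter dataclasses from a config tree.

    Returns a dict with keys ``protocol``, ``reservoir``, ``bg``,
    ``wiring``, ``system``, ``bpdc``, ``arm``.
    """
    bg_cfg = dict(cfg["bg"])
    bg_cfg["layer"] = LayerParams(**bg_cfg["layer"])
    sys_cfg = dict(cfg["system"])
    sys_cfg["oja"] = OjaConfig(**sys_cfg["oja"])
    arm_cfg = {k: _tupleize(v) for k, v in cfg["arm"].items()}
    return {
        "protocol": Protocol(**cfg["protocol"]),
        "reservoir": ReservoirSpec(**cfg["reservoir"]),
        "bg": BGParams(**bg_cfg),
        "wiring": ModuleWiring(**cfg["wiring"]),
        "system": SystemSpec(**sys_cfg),
        "bpdc": BPDCConfig(**cfg["bpdc"]),
        "arm": ArmModel(**arm_cfg),
    }
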