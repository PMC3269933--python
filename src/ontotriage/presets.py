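"""Named run presets, shipped as YAML config files under ``presets/``.

Triage presets encode classifier / n-gram orders / feature count /
training split; ontology-mapping presets encode algorithm / feature count.
The feature-selection method is not part of a preset label and defaults to
mutual information (overridable in any config file).
"""

from __future__ import annotations

from importlib import resources
from typing import Dict, List

import yaml

from .act_pipeline import ActConfig
from .imt_pipeline import ImtConfig

__all__ = ["list_act_presets", "list_imt_presets", "get_act_preset",
           "get_imt_preset", "load_act_config", "load_imt_config",
           "UnknownPresetError"]


class UnknownPresetError(KeyError):
    pass


def _preset_dir():
    return resources.files("ontotriage") / "presets"


def _load_yaml(name: str) -> Dict:
    path = _preset_dir() / f"{name}.yaml"
    if not path.is_file():
        raise UnknownPresetError(
            f"unknown preset {name!r}; valid presets: "
            f"{sorted(list_act_presets() + list_imt_presets())}"
        )
    return yaml.safe_load(path.read_text(encoding="utf-8"))


def _list(task: str) -> List[str]:
    out = []
    for entry in _preset_dir().iterdir():
        if entry.name.endswith(".yaml"):
            data = yaml.safe_load(entry.read_text(encoding="utf-8"))
            if data.get("task") == task:
                out.append(entry.name[: -len(".yaml")])
    return sorted(out)


def list_act_presets() -> List[str]:
    return _list("act")


def list_imt_presets() -> List[str]:
    return _list("imt")


def _act_config_from(data: Dict, seed: int) -> ActConfig:
    fields = {k: v for k, v in data.items() if k != "task"}
    if "orders" in fields:
        fields["orders"] = frozenset(fields["orders"])
    fields.setdefault("seed", seed)
    return ActConfig(**fields)


def _imt_config_from(data: Dict, seed: int) -> ImtConfig:
    fields = {k: v for k, v in data.items() if k != "task"}
    fields.setdefault("seed", seed)
    return ImtConfig(**fields)


def get_act_preset(name: str, seed: int = 0) -> ActConfig:
    data = _load_yaml(name)
    if data.get("task") != "act":
        raise UnknownPresetError(f"{name!r} is not a triage preset")
    return _act_config_from(data, seed)


def get_imt_preset(name: str, seed: int = 0) -> ImtConfig:
    data = _load_yaml(name)
    if data.get("task") != "imt":
        raise UnknownPresetError(f"{name!r} is not an ontology-mapping preset")
    return _imt_config_from(data, seed)


def load_act_config(path, seed: int = 0) -> ActConfig:
    """Load an explicit config file; a ``preset`` key seeds defaults which
    the file's other keys override."""
    data = yaml.safe_load(open(path, encoding="utf-8"))
    preset = data.pop("preset", None)
    if preset is not None:
        base = _load_yaml(preset)
        base.update(data)
        data = base
    data.setdefault("task", "act")
    return _act_config_from(data, seed)


def load_imt_config(path, seed: int = 0) -> ImtConfig:
    data = yaml.safe_load(open(path, encoding="utf-8"))
    preset = data.pop("preset", None)
    if preset is not None:
        base = _load_yaml(preset)
        base.update(data)
        data = base
    data.setdefault("task", "imt")
    return _imt_config_from(data, seed)
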