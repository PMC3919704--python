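"""Configuration and result serialization (JSON/YAML), with atomic writes."""

from __future__ import annotations

import json
import os
import tempfile
from pathlib import Path

import yaml

from .network import DoseSchedule, ParameterSet

__all__ = ["load_config", "dump_config", "atomic_write_text", "ModelConfig"]


class ModelConfig:
    """Model/parameter configuration document.

    Keys: ``variant``, ``parameters`` (name -> value in 1/min), ``dose``
    (``{mode: acute, T_R: ...}`` or ``{mode: fractionated, boundaries: [...]}``)
    and ``breaks_mode``.  Round-trips losslessly through JSON or YAML.
    """

    def __init__(self, variant: str, parameters: ParameterSet,
                 dose: DoseSchedule, breaks_mode: str = "ends"):
        self.variant = variant
        self.parameters = parameters
        self.dose = dose
        self.breaks_mode = breaks_mode

    def to_dict(self) -> dict:
        return {
            "variant": self.variant,
            "parameters": self.parameters.to_dict(),
            "dose": self.dose.to_dict(),
            "breaks_mode": self.breaks_mode,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        for key in ("variant", "parameters"):
            if key not in d:
                raise KeyError(f"config is missing required key {key!r}")
        return cls(
            variant=d["variant"],
            parameters=ParameterSet.from_dict(d["parameters"]),
            dose=DoseSchedule.from_dict(d.get("dose", {"mode": "acute", "T_R": 0.5})),
            breaks_mode=d.get("breaks_mode", "ends"),
        )

    def __eq__(self, other) -> bool:
        return isinstance(other, ModelConfig) and self.to_dict() == other.to_dict()


def load_config(path) -> ModelConfig:
    """Load a model configuration from .json / .yaml / .yml."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix == ".json":
        d = json.loads(text)
    elif path.suffix in (".yaml", ".yml"):
        d = yaml.safe_load(text)
    else:
        raise ValueError(f"unsupported config format {path.suffix!r} (use .json/.yaml)")
    return ModelConfig.from_dict(d)


def dump_config(cfg: ModelConfig, path) -> None:
    path = Path(path)
    d = cfg.to_dict()
    if path.suffix == ".json":
        text = json.dumps(d, indent=2, sort_keys=True) + "\n"
    elif path.suffix in (".yaml", ".yml"):
        text = yaml.safe_dump(d, sort_keys=True)
    else:
        raise ValueError(f"unsupported config format {path.suffix!r} (use .json/.yaml)")
    atomic_write_text(path, text)


def atomic_write_text(path, text: str) -> None:
    """Write via a temp file in the target directory, then rename."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.", suffix=".tmp")
    try:
        with os.fdopen(fd, "w", encoding="utf-8") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise
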