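"""Run configuration: fusion tunables + per-modality preprocessing + paths.

A RunConfig round-trips losslessly through YAML/JSON so that the resolved
config logged next to every output is sufficient to reproduce the run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import preprocessing as pp
from .fusion import FusionConfig

__all__ = ["RunConfig", "apply_preprocessing", "load_config", "save_config"]

#: op name -> callable(img, **params)
_PREPROC_OPS = {
    "dilate": lambda img, **kw: pp.dilate(img),
    "erode": lambda img, **kw: pp.erode(img),
    "shift": lambda img, dx=0, dy=0: pp.shift(img, dx, dy),
    "rotate": lambda img, angle_deg=0.0: pp.rotate(img, angle_deg),
    "sharpen": lambda img, **kw: pp.sharpen(img),
}

#: Default conditioning mirrors the manual workflow: dilation for the
#: structural modality, erosion for the functional one, then sharpening;
#: alignment offsets default to 0 (inputs assumed pre-registered).
DEFAULT_PREPROCESSING = {
    "structural": [{"op": "dilate"}, {"op": "shift", "dx": 0, "dy": 0}, {"op": "sharpen"}],
    "functional": [{"op": "erode"}, {"op": "rotate", "angle_deg": 0.0}, {"op": "sharpen"}],
}


@dataclass(frozen=True)
class RunConfig:
    fusion: FusionConfig = field(default_factory=FusionConfig)
    preprocessing: dict = field(default_factory=lambda: {k: [dict(s) for s in v] for k, v in DEFAULT_PREPROCESSING.items()})
    io: dict = field(default_factory=dict)  # structural/functional/out paths
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "fusion": self.fusion.to_dict(),
            "preprocessing": self.preprocessing,
            "io": dict(self.io),
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(
            fusion=FusionConfig.from_dict(d.get("fusion", {})),
            preprocessing=d.get(
                "preprocessing",
                {k: [dict(s) for s in v] for k, v in DEFAULT_PREPROCESSING.items()},
            ),
            io=dict(d.get("io", {})),
            seed=int(d.get("seed", 0)),
        )


def apply_preprocessing(img: np.ndarray, steps: list[dict]) -> np.ndarray:
    """Apply an ordered list of ``{"op": name, **params}`` steps."""
    for step in steps:
        step = dict(step)
        name = step.pop("op")
        if name not in _PREPROC_OPS:
            raise ValueError(
                f"unknown preprocessing op {name!r}; choose from {sorted(_PREPROC_OPS)}"
            )
        img = _PREPROC_OPS[name](img, **step)
    return img


def load_config(path) -> RunConfig:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.from_dict(data)


def save_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)
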