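"""Flat-file configuration and signal I/O.

Models and pulse trains serialize to flat key-value YAML mappings; complex
signal series are written as CSV with (time_ms, re, im, mag) columns plus
an optional JSON metadata sidecar. Angle conventions: degrees in config
files, radians internally.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .models import (
    PulseTrain,
    SignalSeries,
    SinglePoolModel,
    TwoPoolBMModel,
    TwoPoolMTModel,
)
from .presets import get_preset

__all__ = [
    "model_to_dict",
    "model_from_dict",
    "RunConfig",
    "load_config",
    "save_config",
    "write_signal",
    "read_signal",
]

_MODEL_TYPES = {
    "single": SinglePoolModel,
    "bm": TwoPoolBMModel,
    "mt": TwoPoolMTModel,
}


def model_to_dict(model) -> dict:
    for name, cls in _MODEL_TYPES.items():
        if isinstance(model, cls):
            d = {"type": name}
            d.update(dataclasses.asdict(model))
            return {k: v for k, v in d.items() if v is not None}
    raise TypeError(f"unsupported model type: {type(model).__name__}")


def model_from_dict(d: dict):
    d = dict(d)
    kind = d.pop("type", None)
    if kind not in _MODEL_TYPES:
        raise ValueError(f"model 'type' must be one of {sorted(_MODEL_TYPES)}, got {kind!r}")
    cls = _MODEL_TYPES[kind]
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(d) - valid
    if unknown:
        raise ValueError(f"unknown model fields for type {kind!r}: {sorted(unknown)}")
    return cls(**d)


_SEQUENCE_KEYS = {
    "kind", "tr", "flip_deg", "phi0_deg", "n_pulses", "n_echoes", "esp",
    "b1_scale", "refocus_deg", "n_slices", "dephasing_cycles",
}


@dataclasses.dataclass
class RunConfig:
    """Validated run description: model (preset name or inline mapping),
    sequence block, output path, seed, verbosity."""

    model: object
    sequence: dict
    output: Optional[str] = None
    seed: int = 0
    verbosity: int = 1

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        unknown = set(d) - {"model", "sequence", "output", "seed", "verbosity"}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "model" not in d or "sequence" not in d:
            raise ValueError("config requires 'model' and 'sequence' blocks")
        model = d["model"]
        if isinstance(model, str):
            model = get_preset(model)
        elif isinstance(model, dict):
            model = model_from_dict(model)
        else:
            raise ValueError("'model' must be a preset name or a mapping")
        seq = d["sequence"]
        if not isinstance(seq, dict) or "kind" not in seq:
            raise ValueError("'sequence' must be a mapping with a 'kind' key")
        unknown = set(seq) - _SEQUENCE_KEYS
        if unknown:
            raise ValueError(f"unknown sequence keys: {sorted(unknown)}")
        return cls(
            model=model,
            sequence=seq,
            output=d.get("output"),
            seed=int(d.get("seed", 0)),
            verbosity=int(d.get("verbosity", 1)),
        )

    def to_dict(self) -> dict:
        return {
            "model": model_to_dict(self.model),
            "sequence": dict(self.sequence),
            "output": self.output,
            "seed": self.seed,
            "verbosity": self.verbosity,
        }


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    return RunConfig.from_dict(raw)


def save_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)


def write_signal(series: SignalSeries, path, metadata: Optional[dict] = None) -> None:
    """Write a signal series as CSV; metadata goes to a ``.json`` sidecar."""
    df = pd.DataFrame(
        {
            "time_ms": series.times,
            "re": series.signal.real,
            "im": series.signal.imag,
            "mag": np.abs(series.signal),
        }
    )
    if series.z0_a is not None:
        df["z0_a"] = series.z0_a
    if series.z0_b is not None:
        df["z0_b"] = series.z0_b
    df.to_csv(path, index=False)
    if metadata is not None:
        sidecar = Path(path).with_suffix(".json")
        with open(sidecar, "w") as fh:
            json.dump(metadata, fh, indent=2, default=str)


def read_signal(path) -> SignalSeries:
    df = pd.read_csv(path)
    series = SignalSeries(
        times=df["time_ms"].to_numpy(),
        signal=df["re"].to_numpy() + 1j * df["im"].to_numpy(),
    )
    if "z0_a" in df:
        series.z0_a = df["z0_a"].to_numpy()
    if "z0_b" in df:
        series.z0_b = df["z0_b"].to_numpy()
    return series
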