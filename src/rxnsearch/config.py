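"""Configuration loading, run manifests and seed management."""

from __future__ import annotations

import datetime as _dt
import json
import random
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, field_validator

__all__ = ["AppConfig", "load_config", "set_global_seed", "RunManifest"]


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class EncoderSection(_Section):
    gnn_layers: int = 5
    gnn_hidden: int = 300
    projection_hidden: int = 512
    p: int = 512


class TrainSection(_Section):
    tau: float = 100.0
    M: int = 4096
    learning_rate: float = 1e-4
    weight_decay: float = 1e-8
    max_epochs: int = 200
    patience: int = 20

    @field_validator("M")
    @classmethod
    def _m_positive(cls, v: int) -> int:
        if v < 2:
            raise ValueError("train.M must be at least 2")
        return v

    @field_validator("tau")
    @classmethod
    def _tau_positive(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("train.tau must be positive")
        return v


class PcaSection(_Section):
    evr_threshold: float = 0.95


class SearchSection(_Section):
    K: int = 30


class FeedbackSection(_Section):
    delta: float = 100.0
    lam: float = 0.01
    iterations: int = 100
    learning_rate: float = 1e-4
    momentum: float = 0.9
    weight_decay: float = 1e-8


class AppConfig(_Section):
    seed: int = 0
    encoder: EncoderSection = EncoderSection()
    train: TrainSection = TrainSection()
    pca: PcaSection = PcaSection()
    search: SearchSection = SearchSection()
    feedback: FeedbackSection = FeedbackSection()


def _coerce(value: str) -> Any:
    try:
        return json.loads(value)
    except json.JSONDecodeError:
        return value


def load_config(
    path: str | Path | None = None, overrides: Sequence[str] = ()
) -> AppConfig:
    """Load a YAML/JSON config; an empty or missing file yields all defaults.

    Overrides are dotted ``section.key=value`` strings applied after the
    file. Unknown keys and type mismatches raise validation errors.
    """
    data: dict = {}
    if path is not None:
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
    for item in overrides:
        key, _, raw = item.partition("=")
        if not _:
            raise ValueError(f"override {item!r} must look like key=value")
        node = data
        parts = key.split(".")
        for part in parts[:-1]:
            node = node.setdefault(part, {})
        node[parts[-1]] = _coerce(raw)
    return AppConfig.model_validate(data)


def set_global_seed(seed: int) -> None:
    """Seed every stochastic component used by the package."""
    random.seed(seed)
    np.random.seed(seed % (2**32))


class RunManifest:
    """A re-runnable record of one CLI invocation."""

    def __init__(self, command: str, config: AppConfig, seed: int, **versions: str):
        self.payload = {
            "command": command,
            "config": config.model_dump(),
            "seed": seed,
            "versions": versions,
            "timestamp": _dt.datetime.now(_dt.timezone.utc).isoformat(),
        }

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.payload, indent=2))

    @staticmethod
    def read(path: str | Path) -> dict:
        return json.loads(Path(path).read_text())
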