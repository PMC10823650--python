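"""Run configuration: schema, defaults, YAML loading.

Every knob of the pipeline lives here, grouped by stage.  Unknown keys are
rejected so a typo in a config file fails before any computation.  The
resolved configuration is echoed to the log and written next to every output
for reproducibility.
"""

from __future__ import annotations

import logging
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field

logger = logging.getLogger("circlink")


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class MfConfig(_Strict):
    k: int = Field(default=64, ge=1)
    reg: float = Field(default=0.01, gt=0)
    max_iter: int = Field(default=200, ge=1)
    tol: float = Field(default=1e-5, gt=0)


class ConvConfig(_Strict):
    channels: int = Field(default=8, ge=1)
    width: int = Field(default=3, ge=1)


class FusionConfig(_Strict):
    gamma: float = Field(default=0.5, ge=0.0, le=1.0)


class GraphConfig(_Strict):
    k_neighbors: int = Field(default=10, ge=1)


class TrainSection(_Strict):
    alpha: float = Field(default=0.8, gt=0.0, lt=1.0)
    epochs: int = Field(default=500, ge=1)
    lr: float = Field(default=0.001, gt=0)


class ModelSection(_Strict):
    hidden_dim: int = Field(default=64, ge=1)
    latent_dim: int = Field(default=32, ge=1)


class RunConfig(_Strict):
    """Fully resolved pipeline configuration."""

    mf: MfConfig = MfConfig()
    conv: ConvConfig = ConvConfig()
    fusion: FusionConfig = FusionConfig()
    graph: GraphConfig = GraphConfig()
    train: TrainSection = TrainSection()
    model: ModelSection = ModelSection()
    seed: int = 0

    def dump_yaml(self) -> str:
        return yaml.safe_dump(self.model_dump(), sort_keys=False)


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    """Load a YAML config file, apply overrides, validate, and log the result.

    With no file and no overrides, returns the documented defaults
    (alpha = 0.8, lr = 0.001, gamma = 0.5, k = 64, epochs = 500, ...).
    """
    data: dict = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text())
        if raw is not None:
            if not isinstance(raw, dict):
                raise ValueError(f"config file {path} must contain a mapping")
            data = raw
    for dotted, value in (overrides or {}).items():
        node = data
        *groups, leaf = dotted.split(".")
        for g in groups:
            node = node.setdefault(g, {})
        node[leaf] = value
    cfg = RunConfig.model_validate(data)
    logger.info("resolved config:\n%s", cfg.dump_yaml())
    return cfg
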