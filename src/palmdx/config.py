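"""Experiment configuration: YAML schema, defaults and validation.

Defaults reproduce the reference training setup: 460-pixel input patches,
IIM weights λ1 = 0.2 / λ2 = 0.4, Adam (l0 = 0.01, β1 = 0.9, β2 = 0.999,
decay 0, batch 32), the five-plateau learning-rate schedule, and up to 500
epochs.  A single global seed is fanned out to named substreams (data
generation, splitting, initialization, batch order).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .losses import ScheduleConfig
from .model import ModelConfig
from .synth import GeneratorConfig


class ConfigError(ValueError):
    pass


@dataclass
class PreprocessConfig:
    coverage: float = 1.0
    hard_limit: int | None = 460
    input_side: int = 460


@dataclass
class TrainingBlock:
    epochs: int = 500
    train_fraction: float = 0.8


@dataclass
class ExperimentConfig:
    seed: int = 0
    out_dir: str = "runs"
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    schedule: ScheduleConfig = field(default_factory=ScheduleConfig)
    training: TrainingBlock = field(default_factory=TrainingBlock)

    def resolved(self) -> dict:
        d = {"seed": self.seed, "out_dir": self.out_dir,
             "generator": asdict(self.generator),
             "preprocess": asdict(self.preprocess),
             "model": asdict(self.model),
             "schedule": asdict(self.schedule),
             "training": asdict(self.training)}
        d["model"]["am_levels"] = list(self.model.am_levels)
        d["schedule"]["pieces"] = [list(p) for p in self.schedule.pieces]
        return d


_BLOCKS = {"generator": GeneratorConfig, "preprocess": PreprocessConfig,
           "model": ModelConfig, "schedule": ScheduleConfig,
           "training": TrainingBlock}


def _build_block(name: str, cls, data: dict):
    fields = {f for f in cls.__dataclass_fields__}
    unknown = set(data) - fields
    if unknown:
        raise ConfigError(f"config block '{name}': unknown field(s) {sorted(unknown)}")
    coerced = dict(data)
    for key in ("am_levels", "class_proportions", "delta_mean", "delta_sd"):
        if key in coerced and isinstance(coerced[key], list):
            coerced[key] = tuple(coerced[key])
    if "pieces" in coerced:
        coerced["pieces"] = tuple((int(a), float(b)) for a, b in coerced["pieces"])
    try:
        return cls(**coerced)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"config block '{name}': {exc}") from exc


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> ExperimentConfig:
    """Load YAML (optional) and apply flat overrides like ``{"model.variant": "osn"}``."""
    data: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text())
        if loaded is not None:
            if not isinstance(loaded, dict):
                raise ConfigError(f"{path}: top level must be a mapping")
            data = loaded
    for key, value in (overrides or {}).items():
        node = data
        parts = key.split(".")
        for p in parts[:-1]:
            node = node.setdefault(p, {})
        node[parts[-1]] = value
    unknown = set(data) - set(_BLOCKS) - {"seed", "out_dir"}
    if unknown:
        raise ConfigError(f"unknown top-level config field(s): {sorted(unknown)}")
    kwargs = {"seed": int(data.get("seed", 0)), "out_dir": str(data.get("out_dir", "runs"))}
    for name, cls in _BLOCKS.items():
        block = data.get(name, {})
        if not isinstance(block, dict):
            raise ConfigError(f"config block '{name}' must be a mapping")
        kwargs[name] = _build_block(name, cls, block)
    return ExperimentConfig(**kwargs)


def freeze_config(cfg: ExperimentConfig, out_dir: str | Path) -> Path:
    """Write the fully resolved config beside the artifacts it produced."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / "config.resolved.yaml"
    path.write_text(yaml.safe_dump(cfg.resolved(), sort_keys=True))
    return path
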