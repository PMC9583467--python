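"""Run configuration: one YAML file covering generator, template, model, training.

Schema (all sections and keys optional; unknown keys are rejected)::

    seed: 0
    generator:            # see mode.synthetic.GeneratorConfig
      n_records: 513
      noise_rate: 0.02
    template:             # global template geometry
      p: 8
      r: 96
      c: 96
    model:                # see mode.models.ModelConfig
      n: 64
      L: 2
    train:                # see mode.training.TrainConfig
      batch_size: 32
      aux: both
      schedule: independent

A top-level ``seed`` propagates into the generator, template and training
seeds so one integer reproduces a whole run.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Optional

import yaml

from .models import ModelConfig
from .synthetic import GeneratorConfig
from .training import TrainConfig


@dataclass
class TemplateConfig:
    p: int = 8
    r: int = 96
    c: int = 96

    def validate(self) -> None:
        if min(self.p, self.r, self.c) < 1:
            raise ValueError("template dimensions must be positive")


@dataclass
class RunConfig:
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    template: TemplateConfig = field(default_factory=TemplateConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    seed: int = 0

    def apply_seed(self, seed: int) -> None:
        self.seed = seed
        self.generator.seed = seed
        self.train.seed = seed

    def validate(self) -> None:
        self.generator.validate()
        self.template.validate()
        self.train.validate()
        if self.model.n > min(self.template.r, self.template.c):
            raise ValueError("model hidden size exceeds template extent")


def _fill(dc_type, values: dict):
    allowed = {f.name for f in fields(dc_type)}
    unknown = set(values) - allowed
    if unknown:
        raise ValueError(f"unknown {dc_type.__name__} keys: {sorted(unknown)}")
    # YAML lists for tuple-typed fields
    coerced = {k: tuple(v) if isinstance(v, list) else v for k, v in values.items()}
    return dc_type(**coerced)


def load_config(path: Optional[str] = None, seed: Optional[int] = None
                ) -> RunConfig:
    raw = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping")
    unknown = set(raw) - {"generator", "template", "model", "train", "seed"}
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    cfg = RunConfig(generator=_fill(GeneratorConfig, raw.get("generator", {})),
                    template=_fill(TemplateConfig, raw.get("template", {})),
                    model=_fill(ModelConfig, raw.get("model", {})),
                    train=_fill(TrainConfig, raw.get("train", {})),
                    seed=int(raw.get("seed", 0)))
    if seed is not None:
        cfg.apply_seed(seed)
    else:
        cfg.apply_seed(cfg.seed)
    cfg.validate()
    return cfg


def _listify(obj):
    if isinstance(obj, dict):
        return {k: _listify(v) for k, v in obj.items()}
    if isinstance(obj, tuple):
        return [_listify(v) for v in obj]
    return obj


def dump_config(cfg: RunConfig, path) -> None:
    from dataclasses import asdict
    with open(path, "w") as fh:
        yaml.safe_dump(_listify({"generator": asdict(cfg.generator),
                                 "template": asdict(cfg.template),
                                 "model": asdict(cfg.model),
                                 "train": asdict(cfg.train),
                                 "seed": cfg.seed}), fh, sort_keys=False)
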