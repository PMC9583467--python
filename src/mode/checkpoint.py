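"""Single-file checkpoints for the template, kernels and model parameters.

A checkpoint is an ``.npz`` archive holding every parameter array plus a
JSON metadata block (model configuration, per-task seeds, template geometry
and seed), which is enough to rebuild the module graph and restore every
tensor bit-exactly.  Kernel tensors are reached through each model's
parameter list, so the template's bindings are restored implicitly by
rebuilding the models in their construction order.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from typing import Dict, Optional, Tuple

import numpy as np

from .models import ATRModel, ModelConfig, SeverityModel, SummaryModel
from .sps import Template

_MODEL_CLASSES = {"summary": SummaryModel, "severity": SeverityModel,
                  "atr": ATRModel}


def save_checkpoint(path, template: Optional[Template], models: Dict[str, object],
                    model_cfg: ModelConfig, seeds: Dict[str, int],
                    extra_meta: Optional[dict] = None) -> None:
    arrays: Dict[str, np.ndarray] = {}
    meta = {"model_cfg": asdict(model_cfg),
            "tasks": list(models.keys()),
            "seeds": {k: int(v) for k, v in seeds.items()},
            "template": None,
            "extra": extra_meta or {}}
    if template is not None:
        meta["template"] = {"shape": list(template.shape),
                            "seed": template.seed}
        arrays["template"] = template.values.data
    for task, model in models.items():
        for i, p in enumerate(model.parameters()):
            arrays[f"{task}.{i:04d}"] = p.data
    arrays["__meta__"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    with open(path, "wb") as fh:
        np.savez(fh, **arrays)


def load_checkpoint(path) -> Tuple[Optional[Template], Dict[str, object],
                                   ModelConfig, dict]:
    with np.load(path) as npz:
        meta = json.loads(bytes(npz["__meta__"]).decode())
        model_cfg = ModelConfig(**meta["model_cfg"])
        template = None
        if meta["template"] is not None:
            p, r, c = meta["template"]["shape"]
            template = Template.create(p, r, c, seed=meta["template"]["seed"] or 0)
            template.values.data[...] = npz["template"]
        models: Dict[str, object] = {}
        for task in meta["tasks"]:
            model = _MODEL_CLASSES[task](model_cfg, template,
                                         seed=meta["seeds"][task])
            for i, par in enumerate(model.parameters()):
                stored = npz[f"{task}.{i:04d}"]
                if stored.shape != par.data.shape:
                    raise ValueError(
                        f"checkpoint mismatch for {task} parameter {i}: "
                        f"stored {stored.shape} vs model {par.data.shape}")
                par.data[...] = stored
            models[task] = model
    return template, models, model_cfg, meta
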