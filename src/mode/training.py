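"""Losses, the MLL metric, the learning-rate schedule and task orchestration.

Two orchestration modes mirror the framework's training policies:

* **independent** — each task is trained to completion in the fixed order
  Summary -> Severity -> ATR.  Only the global template carries over between
  phases (optimizer state is reset), so the main task starts from a template
  already shaped by the auxiliaries.
* **collaborative** — one pass per task per epoch in the same order, with
  the weighted sum of the task losses backpropagated per batch.

Sequence tasks use mean token-level cross entropy over non-pad positions;
the severity regression uses mean squared error on labels normalized to
[0, 1].  Performance is reported as MLL = -ln(loss), larger is better.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .autodiff import Tensor, cross_entropy_logits
from .data import ReportRecord, build_teacher, pad_batch
from .models import ATRModel, ModelConfig, SeverityModel, SummaryModel
from .sps import Template, count_parameters

TASK_ORDER = ("summary", "severity", "atr")
AUX_MODES = ("none", "summary_only", "severity_only", "both")
SCHEDULES = ("independent", "collaborative")


@dataclass
class TrainConfig:
    """Optimization settings; defaults follow the reference training recipe."""

    initial_lr: float = 0.01
    epoch_max: int = 40          # horizon of the decay schedule
    lr_decay: float = 0.8
    lr_base: float = 0.01
    batch_size: int = 32
    aux: str = "both"            # none | summary_only | severity_only | both
    schedule: str = "independent"
    flags_enabled: bool = True
    loss_weights: Tuple[float, float, float] = (1.0, 1.0, 1.0)  # summary, severity, atr
    epochs_summary: Optional[int] = None   # default: epoch_max
    epochs_severity: Optional[int] = None
    epochs_atr: Optional[int] = None
    # per-task initial rates for the independent schedule (None -> initial_lr);
    # tasks differ widely in how hot they can run
    lr_summary: Optional[float] = None
    lr_severity: Optional[float] = None
    lr_atr: Optional[float] = None
    grad_clip: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.epoch_max < 1:
            raise ValueError("epoch_max must be >= 1")
        if any(w < 0 for w in self.loss_weights):
            raise ValueError("loss weights must be non-negative")
        if self.aux not in AUX_MODES:
            raise ValueError(f"unknown aux mode {self.aux!r}")
        if self.schedule not in SCHEDULES:
            raise ValueError(f"unknown schedule {self.schedule!r}")

    def epochs_for(self, task: str) -> int:
        value = {"summary": self.epochs_summary,
                 "severity": self.epochs_severity,
                 "atr": self.epochs_atr}[task]
        return self.epoch_max if value is None else value

    def initial_lr_for(self, task: str) -> float:
        value = {"summary": self.lr_summary, "severity": self.lr_severity,
                 "atr": self.lr_atr}[task]
        return self.initial_lr if value is None else value

    def enabled_tasks(self) -> List[str]:
        aux = {"none": [], "summary_only": ["summary"],
               "severity_only": ["severity"],
               "both": ["summary", "severity"]}[self.aux]
        return aux + ["atr"]


@dataclass
class TaskMetrics:
    """Per-epoch training trace and final evaluation for one task."""

    task: str
    train_losses: List[float] = field(default_factory=list)
    dev_mll: List[float] = field(default_factory=list)
    test_mll: Optional[float] = None
    param_report: Optional[object] = None


class TrainingDivergence(RuntimeError):
    def __init__(self, task: str, epoch: int, step: int, loss: float):
        super().__init__(f"non-finite loss in task {task!r} at epoch {epoch}, "
                         f"step {step}: {loss}")
        self.state = {"task": task, "epoch": epoch, "step": step, "loss": loss}


def lr_at_epoch(i: int, cfg: TrainConfig) -> float:
    """Learning rate for epoch ``i`` (0-based) under the decay recurrence

        lr_{i+1} = decay * lr_i * base^((i + 0.01) / (epoch_max + 0.01))

    with lr_0 = initial_lr; strictly decreasing in ``i``.
    """
    if i < 0:
        raise ValueError("epoch index must be >= 0")
    lr = cfg.initial_lr
    for j in range(i):
        lr = cfg.lr_decay * lr * cfg.lr_base ** ((j + 0.01) / (cfg.epoch_max + 0.01))
    return lr


def mll_score(loss: float) -> float:
    """Minus log loss, -ln(loss); larger is better."""
    if loss <= 0:
        raise ValueError(f"loss must be positive, got {loss}")
    return float(-np.log(loss))


class Adam:
    """Adam with global-norm gradient clipping over all optimized tensors."""

    def __init__(self, params: Sequence[Tensor], beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8, clip: float = 1.0):
        self.params = list(params)
        self.beta1, self.beta2, self.eps, self.clip = beta1, beta2, eps, clip
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self, lr: float) -> None:
        self.t += 1
        grads = [p.grad if p.grad is not None else np.zeros_like(p.data)
                 for p in self.params]
        if self.clip is not None and self.clip > 0:
            norm = float(np.sqrt(sum(float((g * g).sum()) for g in grads)))
            if norm > self.clip:
                scale = self.clip / norm
                grads = [g * scale for g in grads]
        b1, b2 = self.beta1, self.beta2
        corr1 = 1 - b1 ** self.t
        corr2 = 1 - b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.data -= lr * (m / corr1) / (np.sqrt(v / corr2) + self.eps)


# ---------------------------------------------------------------------------
# losses


def task_loss(task: str, records: Sequence[ReportRecord], model,
              flags: bool, training: bool = False) -> Tensor:
    """Scalar loss of one task on one batch of records."""
    if task == "summary":
        F, _ = pad_batch([r.finding for r in records])
        t_in, t_out, mask = build_teacher([r.impression for r in records], flags)
        logits = model.forward(F, t_in, training=training)
        return cross_entropy_logits(logits, t_out, mask)
    if task == "severity":
        F, _ = pad_batch([r.finding for r in records])
        I, _ = pad_batch([r.impression for r in records])
        target = np.array([r.severity for r in records], dtype=float) / 5.0
        s = model.forward(F, I, training=training)
        diff = s - Tensor(target)
        return (diff * diff).mean()
    if task == "atr":
        F, _ = pad_batch([r.finding for r in records])
        I, _ = pad_batch([r.impression for r in records])
        t_in, t_out, mask = build_teacher([r.treatment for r in records], flags)
        logits = model.forward(F, I, t_in, training=training)
        return cross_entropy_logits(logits, t_out, mask)
    raise ValueError(f"unknown task {task!r}")


def evaluate(model, records: Sequence[ReportRecord], flags: bool = True,
             batch_size: int = 64) -> float:
    """Teacher-forced MLL on a split; deterministic (dropout off)."""
    total, count = 0.0, 0
    for lo in range(0, len(records), batch_size):
        batch = records[lo:lo + batch_size]
        loss = float(task_loss(model.task, batch, model, flags,
                               training=False).data)
        total += loss * len(batch)
        count += len(batch)
    return mll_score(total / count)


def overfit(task: str, records: Sequence[ReportRecord], model,
            template: Optional[Template] = None, lr: float = 5e-4,
            max_steps: int = 500, flags: bool = True,
            stop_below: Optional[float] = None) -> List[float]:
    """Memorization driver: full-batch Adam at a constant learning rate.

    Used for capacity sanity checks — a consistent generator should let each
    task model drive its training loss to near zero on a handful of records.
    Stops early once ``stop_below`` is reached.  Returns the loss trace.
    """
    params = list(model.parameters())
    if template is not None and model.template is not None:
        params.append(template.values)
    opt = Adam(params, clip=1.0)
    losses: List[float] = []
    for step in range(max_steps):
        opt.zero_grad()
        loss = task_loss(task, records, model, flags, training=True)
        value = float(loss.data)
        if not np.isfinite(value):
            raise TrainingDivergence(task, 0, step, value)
        loss.backward()
        opt.step(lr)
        losses.append(value)
        if stop_below is not None and value < stop_below:
            break
    return losses


# ---------------------------------------------------------------------------
# orchestration


def _make_model(task: str, model_cfg: ModelConfig, template: Optional[Template],
                seed: int):
    cls = {"summary": SummaryModel, "severity": SeverityModel,
           "atr": ATRModel}[task]
    return cls(model_cfg, template, seed=seed)


def _batches(records: Sequence[ReportRecord], batch_size: int,
             rng: np.random.Generator):
    order = rng.permutation(len(records))
    for lo in range(0, len(records), batch_size):
        yield [records[i] for i in order[lo:lo + batch_size]]


def train_task(task: str, split, template: Optional[Template],
               cfg: TrainConfig, *, model=None,
               model_cfg: Optional[ModelConfig] = None,
               epochs: Optional[int] = None,
               log=None) -> TaskMetrics:
    """Train one task for its epoch budget; returns its metrics trace.

    ``split`` is (train_records, dev_records).  Shared weights are
    regenerated from the template on every forward pass, so template,
    kernels and module-local parameters are all updated jointly.
    """
    cfg.validate()
    train_records, dev_records = split
    if model is None:
        model = _make_model(task, model_cfg, template, seed=cfg.seed)
    params = list(model.parameters())
    if template is not None and model.template is not None:
        params.append(template.values)
    opt = Adam(params, clip=cfg.grad_clip)
    rng = np.random.default_rng([cfg.seed, {"summary": 1, "severity": 2,
                                            "atr": 3}[task]])
    metrics = TaskMetrics(task=task)
    n_epochs = cfg.epochs_for(task) if epochs is None else epochs
    from dataclasses import replace
    phase_cfg = replace(cfg, initial_lr=cfg.initial_lr_for(task))
    for epoch in range(n_epochs):
        lr = lr_at_epoch(epoch, phase_cfg)
        epoch_losses = []
        for step, batch in enumerate(_batches(train_records, cfg.batch_size, rng)):
            opt.zero_grad()
            loss = task_loss(task, batch, model, cfg.flags_enabled, training=True)
            value = float(loss.data)
            if not np.isfinite(value):
                raise TrainingDivergence(task, epoch, step, value)
            loss.backward()
            opt.step(lr)
            epoch_losses.append(value)
        metrics.train_losses.append(float(np.mean(epoch_losses)))
        if dev_records:
            metrics.dev_mll.append(evaluate(model, dev_records,
                                            cfg.flags_enabled))
        if log is not None:
            log(task=task, epoch=epoch, lr=lr,
                loss=metrics.train_losses[-1],
                dev_mll=metrics.dev_mll[-1] if metrics.dev_mll else float("nan"))
    return metrics


def run_schedule(cfg: TrainConfig, splits, model_cfg: ModelConfig,
                 template: Optional[Template] = None, log=None
                 ) -> Dict[str, object]:
    """Run the full multi-task recipe; returns metrics, models and template.

    ``splits`` is (train, dev, test).  Independent mode trains each enabled
    task fully, in the order Summary -> Severity -> ATR, over the evolving
    shared template with a fresh optimizer per phase.  Collaborative mode
    sums the enabled tasks' weighted losses per batch.  The test MLL of the
    ATR model is always reported.
    """
    cfg.validate()
    train, dev, test = splits
    tasks = cfg.enabled_tasks()
    if template is None and model_cfg.templated:
        raise ValueError("templated models need a template")
    # fixed per-task seed offsets so a task's initialization is identical
    # across aux modes (paired comparisons differ only in the schedule)
    offsets = {t: i for i, t in enumerate(TASK_ORDER)}
    models = {t: _make_model(t, model_cfg, template, seed=cfg.seed + offsets[t])
              for t in tasks}
    results: Dict[str, TaskMetrics] = {}

    if cfg.schedule == "independent":
        for task in tasks:
            results[task] = train_task(task, (train, dev), template, cfg,
                                       model=models[task], log=log)
    else:
        weights = dict(zip(TASK_ORDER, cfg.loss_weights))
        params: List[Tensor] = []
        for m in models.values():
            params.extend(m.parameters())
        if template is not None and model_cfg.templated:
            params.append(template.values)
        opt = Adam(params, clip=cfg.grad_clip)
        rng = np.random.default_rng([cfg.seed, 7])
        results = {t: TaskMetrics(task=t) for t in tasks}
        for epoch in range(cfg.epochs_for("atr")):
            lr = lr_at_epoch(epoch, cfg)
            sums = {t: [] for t in tasks}
            for step, batch in enumerate(_batches(train, cfg.batch_size, rng)):
                opt.zero_grad()
                total = None
                for task in tasks:
                    loss = task_loss(task, batch, models[task], cfg.flags_enabled,
                                     training=True)
                    value = float(loss.data)
                    if not np.isfinite(value):
                        raise TrainingDivergence(task, epoch, step, value)
                    sums[task].append(value)
                    weighted = loss * weights[task]
                    total = weighted if total is None else total + weighted
                total.backward()
                opt.step(lr)
            for task in tasks:
                results[task].train_losses.append(float(np.mean(sums[task])))
                if dev:
                    results[task].dev_mll.append(
                        evaluate(models[task], dev, cfg.flags_enabled))
                if log is not None:
                    log(task=task, epoch=epoch, lr=lr,
                        loss=results[task].train_losses[-1],
                        dev_mll=results[task].dev_mll[-1] if dev else float("nan"))

    if test:
        results["atr"].test_mll = evaluate(models["atr"], test, cfg.flags_enabled)
    if template is not None and model_cfg.templated:
        biases = {}
        for m in models.values():
            biases.update(m.local_bias_sizes())
        results["atr"].param_report = count_parameters(template.bindings,
                                                       template, biases)
    return {"metrics": results, "models": models, "template": template}
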