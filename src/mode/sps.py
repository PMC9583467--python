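"""Soft parameter sharing: the global template and the kernel-shape calculus.

All tasks in the framework draw their dense weights from one global tensor,
the *template* ``E`` of shape (p, r, c) — p slices of r x c reals.  Each
linear or convolution module owns a small *SPS kernel* ``M`` and recovers its
weight tensor as

    W = sigma(E (*) M + b)

where ``(*)`` is a valid (no padding, stride 1) cross-correlation over the
two spatial axes, ``b`` is one scalar per output slice and ``sigma`` an
elementwise activation (tanh by default, so generated weights take signed
values).  Because valid correlation shrinks the spatial extent by exactly
``kernel - 1``, a target of shape (p0, r0, c0) pins the kernel shape to

    (p, p0, r - r0 + 1, c - c0 + 1)

which is the whole shape calculus: any module whose weight fits spatially
inside the template can be carved out of it.  Training updates the template
through every kernel, so tasks trained earlier leave their knowledge where
later tasks will read it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Literal, Mapping, Optional, Tuple

import numpy as np

from .autodiff import Tensor, sps_correlate

Activation = Literal["identity", "tanh", "sigmoid"]

_ACTIVATIONS = {
    "identity": lambda t: t,
    "tanh": lambda t: t.tanh(),
    "sigmoid": lambda t: t.sigmoid(),
}


class ShapeError(ValueError):
    """A target does not fit the template, or shapes are inconsistent."""


def xavier_uniform(shape: Tuple[int, ...], fan_in: int, fan_out: int,
                   rng: np.random.Generator) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def kernel_shape_for_target(template_shape: Tuple[int, int, int],
                            target_shape: Tuple[int, int, int]) -> Tuple[int, int, int, int]:
    """Kernel shape (p, p0, kh, kw) that carves ``target_shape`` from the template.

    ``template_shape`` is (p, r, c); ``target_shape`` is (p0, r0, c0).  The
    spatial extents follow the valid-correlation output formula inverted:
    kh = r - r0 + 1, kw = c - c0 + 1.
    """
    p, r, c = template_shape
    p0, r0, c0 = target_shape
    if p0 < 1:
        raise ShapeError(f"target slice count p0={p0} must be >= 1")
    if r0 > r:
        raise ShapeError(f"target rows r0={r0} exceed template rows r={r}")
    if c0 > c:
        raise ShapeError(f"target cols c0={c0} exceed template cols c={c}")
    if r0 < 1 or c0 < 1:
        raise ShapeError(f"target spatial extent ({r0}, {c0}) must be >= 1")
    return (p, p0, r - r0 + 1, c - c0 + 1)


@dataclass
class Template:
    """The global shared parameter store: p slices of r x c reals."""

    values: Tensor
    seed: Optional[int] = None
    bindings: Dict[str, "ModuleBinding"] = field(default_factory=dict)

    @classmethod
    def create(cls, p: int, r: int, c: int, seed: int = 0) -> "Template":
        if p < 1 or r < 1 or c < 1:
            raise ShapeError(f"template shape ({p}, {r}, {c}) must be positive")
        rng = np.random.default_rng(seed)
        values = Tensor(xavier_uniform((p, r, c), fan_in=r, fan_out=c, rng=rng),
                        requires_grad=True)
        return cls(values=values, seed=seed)

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def checksum(self) -> float:
        """Cheap fingerprint for phase-boundary change detection."""
        return float(np.abs(self.values.data).sum())


@dataclass
class SPSKernel:
    """Per-module kernel M plus its per-slice bias and activation."""

    values: Tensor                       # (p, p0, kh, kw)
    bias: Tensor                         # (p0,)
    activation: Activation
    target_shape: Tuple[int, int, int]   # (p0, r0, c0)

    def n_params(self) -> int:
        return int(self.values.data.size + self.bias.data.size)


@dataclass
class ModuleBinding:
    """Registration of one templated module against the global template."""

    module_id: str
    kind: Literal["linear", "conv1d"]
    target_shape: Tuple[int, int, int]
    kernel: SPSKernel
    templated: bool = True


def sps_generate(template: Template, kernel: SPSKernel) -> Tensor:
    """Generate a weight tensor of ``kernel.target_shape`` from the template.

    Differentiable: gradients of any function of the output flow into both
    the kernel and the template.
    """
    if not np.isfinite(template.values.data).all():
        raise FloatingPointError("template contains non-finite entries")
    expected = kernel_shape_for_target(template.shape, kernel.target_shape)
    if tuple(kernel.values.shape) != expected:
        raise ShapeError(
            f"kernel shape {tuple(kernel.values.shape)} inconsistent with "
            f"template {template.shape} and target {kernel.target_shape}; "
            f"expected {expected}")
    raw = sps_correlate(template.values, kernel.values)
    raw = raw + kernel.bias.reshape(-1, 1, 1)
    return _ACTIVATIONS[kernel.activation](raw)


def bind_module(module_id: str,
                kind: Literal["linear", "conv1d"],
                target_shape: Tuple[int, ...],
                template: Template,
                rng: Optional[np.random.Generator] = None,
                activation: Activation = "tanh") -> ModuleBinding:
    """Create and register a fresh Xavier-initialized kernel for one module.

    ``target_shape`` is (n, m) for a linear weight — mapped to the canonical
    (p0=1, r0=n, c0=m) — or (n, n, k) for a width-k convolution kernel,
    mapped to (p0=k, r0=n, c0=n).
    """
    if module_id in template.bindings:
        raise ValueError(f"module_id {module_id!r} already bound")
    if kind == "linear":
        n, m = target_shape
        canonical = (1, n, m)
    elif kind == "conv1d":
        n, n2, k = target_shape
        if n != n2:
            raise ShapeError("conv1d targets must have equal in/out channels")
        canonical = (k, n, n)
    else:
        raise ValueError(f"unknown module kind {kind!r}")
    p, p0, kh, kw = kernel_shape_for_target(template.shape, canonical)
    rng = rng if rng is not None else np.random.default_rng(0)
    fan_in = p * kh * kw
    fan_out = p0 * kh * kw
    values = Tensor(xavier_uniform((p, p0, kh, kw), fan_in, fan_out, rng),
                    requires_grad=True)
    bias = Tensor(np.zeros(p0), requires_grad=True)
    kernel = SPSKernel(values=values, bias=bias, activation=activation,
                       target_shape=canonical)
    binding = ModuleBinding(module_id=module_id, kind=kind,
                            target_shape=canonical, kernel=kernel)
    template.bindings[module_id] = binding
    return binding


@dataclass
class ParamReport:
    """Parameter accounting: shared (template + kernels) vs dense equivalent."""

    template_params: int
    per_module_kernel_params: Dict[str, int]
    dense_equivalent_params: int
    total_shared: int

    def rows(self):
        for mid, n in self.per_module_kernel_params.items():
            yield mid, n


def count_parameters(bindings: Mapping[str, ModuleBinding],
                     template: Template,
                     module_local_biases: Optional[Mapping[str, int]] = None
                     ) -> ParamReport:
    """Count shared parameters and what the same modules would cost dense.

    The template is counted once globally.  Each binding contributes its
    kernel entries plus p0 SPS-bias scalars; module-local activation biases
    (given as module_id -> length) are counted per module on both sides of
    the comparison.
    """
    module_local_biases = dict(module_local_biases or {})
    template_params = int(np.prod(template.shape))
    per_module: Dict[str, int] = {}
    dense = 0
    for mid, binding in bindings.items():
        local = module_local_biases.get(mid, 0)
        per_module[mid] = binding.kernel.n_params() + local
        p0, r0, c0 = binding.target_shape
        dense += p0 * r0 * c0 + local
    total_shared = template_params + sum(per_module.values())
    return ParamReport(template_params=template_params,
                       per_module_kernel_params=per_module,
                       dense_equivalent_params=dense,
                       total_shared=total_shared)
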