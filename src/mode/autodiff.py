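"""Minimal reverse-mode automatic differentiation over numpy arrays.

The framework regenerates every shared weight tensor from a global template
on each training step, so gradients must flow from task losses through the
generated weights back into both the per-module kernels and the template.
A small tape-based autodiff core is sufficient for that: dense ops are plain
numpy, and the two convolution primitives (template carving and temporal
convolution) carry hand-written adjoints built on scipy's FFT convolution.

All tensors are float64.  Graphs are built eagerly; ``Tensor.backward()``
runs a topological sweep and accumulates gradients on every leaf with
``requires_grad=True``.
"""

from __future__ import annotations

from typing import Callable, Iterable, Optional, Sequence, Tuple

import numpy as np
from scipy import fft


def _unbroadcast(grad: np.ndarray, shape: Tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (the adjoint of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndim_diff = grad.ndim - len(shape)
    if ndim_diff > 0:
        grad = grad.sum(axis=tuple(range(ndim_diff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array plus the bookkeeping needed for reverse-mode autodiff."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = bool(requires_grad)
        self._backward: Optional[Callable[[np.ndarray], None]] = None
        self._parents: Tuple["Tensor", ...] = ()

    # -- construction helpers -------------------------------------------------

    @property
    def shape(self) -> Tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(grad)  # defensive copy; caller may own grad
        else:
            self.grad += grad

    # -- graph construction ----------------------------------------------------

    @staticmethod
    def _make(data: np.ndarray, parents: Sequence["Tensor"],
              backward: Callable[[np.ndarray], None]) -> "Tensor":
        out = Tensor(data)
        out.requires_grad = any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # -- arithmetic -------------------------------------------------------------

    def __add__(self, other) -> "Tensor":
        other = other if isinstance(other, Tensor) else Tensor(other)
        data = self.data + other.data

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        return Tensor._make(data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(-g)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other) -> "Tensor":
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other) -> "Tensor":
        return Tensor(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = other if isinstance(other, Tensor) else Tensor(other)
        data = self.data * other.data

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        return Tensor._make(data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        if isinstance(other, Tensor):
            return self * other ** -1.0
        return self * (1.0 / float(other))

    def __pow__(self, exponent: float) -> "Tensor":
        data = self.data ** exponent

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g * exponent * self.data ** (exponent - 1.0))

        return Tensor._make(data, (self,), backward)

    def __matmul__(self, other: "Tensor") -> "Tensor":
        other = other if isinstance(other, Tensor) else Tensor(other)
        data = self.data @ other.data

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accumulate(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accumulate(_unbroadcast(gb, other.shape))

        return Tensor._make(data, (self, other), backward)

    # -- elementwise nonlinearities ---------------------------------------------

    def tanh(self) -> "Tensor":
        data = np.tanh(self.data)

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g * (1.0 - data * data))

        return Tensor._make(data, (self,), backward)

    def sigmoid(self) -> "Tensor":
        data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g * data * (1.0 - data))

        return Tensor._make(data, (self,), backward)

    def relu(self) -> "Tensor":
        data = np.maximum(self.data, 0.0)

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g * (self.data > 0.0))

        return Tensor._make(data, (self,), backward)

    def exp(self) -> "Tensor":
        data = np.exp(self.data)

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g * data)

        return Tensor._make(data, (self,), backward)

    def log(self) -> "Tensor":
        data = np.log(self.data)

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g / self.data)

        return Tensor._make(data, (self,), backward)

    # -- reductions and shaping -------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g: np.ndarray) -> None:
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.shape).copy())

        return Tensor._make(data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            n = self.data.size
        else:
            n = self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        data = self.data.reshape(shape)
        src_shape = self.shape

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g.reshape(src_shape))

        return Tensor._make(data, (self,), backward)

    def swapaxes(self, a: int, b: int) -> "Tensor":
        data = np.swapaxes(self.data, a, b)

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(np.swapaxes(g, a, b))

        return Tensor._make(data, (self,), backward)

    def __getitem__(self, idx) -> "Tensor":
        data = self.data[idx]
        parts = idx if isinstance(idx, tuple) else (idx,)
        basic = all(isinstance(p, (int, slice, type(None), type(Ellipsis)))
                    for p in parts)

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                if self.grad is None:
                    self.grad = np.zeros_like(self.data)
                if basic:
                    # basic indexing touches each element at most once, so
                    # the slice gradient can be added into the buffer in place
                    self.grad[idx] += g
                else:
                    np.add.at(self.grad, idx, g)

        return Tensor._make(data, (self,), backward)

    # -- backward sweep ----------------------------------------------------------

    def backward(self, grad: Optional[np.ndarray] = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)
                # interior activations: free adjoints to bound memory
                if node is not self:
                    node.grad = None
                node._backward = None
                node._parents = ()


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    """Differentiable concatenation along ``axis``."""
    tensors = list(tensors)
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g: np.ndarray) -> None:
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis if axis >= 0 else g.ndim + axis] = slice(lo, hi)
                t._accumulate(g[tuple(idx)])

    return Tensor._make(data, tensors, backward)


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = list(tensors)
    data = np.stack([t.data for t in tensors], axis=axis)

    def backward(g: np.ndarray) -> None:
        parts = np.moveaxis(g, axis, 0)
        for t, part in zip(tensors, parts):
            if t.requires_grad:
                t._accumulate(part)

    return Tensor._make(data, tensors, backward)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable softmax with a fused adjoint."""
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    data = e / e.sum(axis=axis, keepdims=True)

    def backward(g: np.ndarray) -> None:
        if x.requires_grad:
            dot = (g * data).sum(axis=axis, keepdims=True)
            x._accumulate(data * (g - dot))

    return Tensor._make(data, (x,), backward)


def embedding_lookup(table: Tensor, ids: np.ndarray) -> Tensor:
    """Row gather ``table[ids]`` with scatter-add adjoint."""
    ids = np.asarray(ids)
    data = table.data[ids]

    def backward(g: np.ndarray) -> None:
        if table.requires_grad:
            if table.grad is None:
                table.grad = np.zeros_like(table.data)
            # segment-sum scatter: sort ids once, reduce contiguous runs
            flat = ids.reshape(-1)
            gf = g.reshape(-1, g.shape[-1])
            order = np.argsort(flat, kind="stable")
            sorted_ids = flat[order]
            starts = np.flatnonzero(
                np.r_[True, sorted_ids[1:] != sorted_ids[:-1]])
            sums = np.add.reduceat(gf[order], starts, axis=0)
            table.grad[sorted_ids[starts]] += sums

    return Tensor._make(data, (table,), backward)


def sps_correlate(template: Tensor, kernel: Tensor) -> Tensor:
    """Valid cross-correlation carving a target tensor out of the template.

    ``template`` has shape (p, r, c); ``kernel`` has shape (p, p0, kh, kw).
    The output has shape (p0, r - kh + 1, c - kw + 1):

        out[q, i, j] = sum_p sum_{u,v} template[p, i+u, j+v] * kernel[p, q, u, v]

    Implemented with circular FFTs of size exactly (r, c): because the
    kernel never exceeds the template, the retained output indices are free
    of wraparound, and the full-size backward convolution has length exactly
    (r, c) as well.  The template and kernel spectra are computed once and
    shared between the forward pass and both adjoints.
    """
    E, M = template.data, kernel.data
    p, r, c = E.shape
    _, p0, kh, kw = M.shape
    r0, c0 = r - kh + 1, c - kw + 1
    if kh == 1 and kw == 1:
        # pure slice mixing: computed exactly (one-hot kernels must
        # reproduce template slices bit-for-bit)
        mix = M[:, :, 0, 0]                      # (p, p0)
        data = np.tensordot(mix, E, axes=(0, 0))  # (p0, r, c)

        def backward_1x1(g: np.ndarray) -> None:
            if template.requires_grad:
                template._accumulate(np.tensordot(mix, g, axes=(1, 0)))
            if kernel.requires_grad:
                dmix = np.einsum("prc,qrc->pq", E, g, optimize=True)
                kernel._accumulate(dmix[:, :, None, None])

        return Tensor._make(data, (template, kernel), backward_1x1)
    sh = (r, c)
    Ef = fft.rfft2(E, sh)                       # (p, r, c//2+1)
    Mf = fft.rfft2(M, sh)                       # (p, p0, r, c//2+1)
    # circular correlation = IFFT(E^ * conj(M^)); no wrap on kept indices
    data = fft.irfft2(np.einsum("pxy,pqxy->qxy", Ef, Mf.conj(), optimize=True),
                      sh)[:, :r0, :c0]

    def backward(g: np.ndarray) -> None:
        Gf = fft.rfft2(g, sh)                   # (p0, r, c//2+1)
        if template.requires_grad:
            # dE[p] = sum_q full_conv(g[q], M[p, q]), length exactly (r, c)
            dE = fft.irfft2(np.einsum("qxy,pqxy->pxy", Gf, Mf, optimize=True), sh)
            template._accumulate(dE)
        if kernel.requires_grad:
            # dM[p, q] = valid corr(E[p], g[q]), kept extent (kh, kw).
            # Two-stage inverse: truncate to the kh needed rows after the
            # first (complex) pass so the second pass transforms kh rows,
            # not r.
            prod = Ef[:, None] * Gf.conj()[None, :]
            rows = fft.ifft(prod, axis=-2)[..., :kh, :]
            dM = fft.irfft(rows, n=c, axis=-1)[..., :kw]
            kernel._accumulate(dM)

    return Tensor._make(data, (template, kernel), backward)


def conv1d_same(x: Tensor, weight: Tensor, bias: Tensor) -> Tensor:
    """Same-padded temporal convolution.

    ``x`` is (B, T, n_in); ``weight`` is (n_in, n_out, k); ``bias`` is (n_out,).
    Output is (B, T, n_out):

        out[b, t, m] = sum_k sum_n xp[b, t+k, n] * weight[n, m, k] + bias[m]
    """
    B, T, n_in = x.data.shape
    _, n_out, k = weight.data.shape
    lp = (k - 1) // 2
    rp = k - 1 - lp
    xp = np.pad(x.data, ((0, 0), (lp, rp), (0, 0)))
    windows = np.lib.stride_tricks.sliding_window_view(xp, k, axis=1)  # (B,T,n_in,k)
    data = np.einsum("btnk,nmk->btm", windows, weight.data, optimize=True)
    data += bias.data

    def backward(g: np.ndarray) -> None:
        if weight.requires_grad:
            dW = np.einsum("btnk,btm->nmk", windows, g, optimize=True)
            weight._accumulate(dW)
        if bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 1)))
        if x.requires_grad:
            dxp = np.zeros_like(xp)
            for j in range(k):
                dxp[:, j:j + T] += np.einsum("btm,nm->btn", g, weight.data[:, :, j],
                                             optimize=True)
            x._accumulate(dxp[:, lp:lp + T])

    return Tensor._make(data, (x, weight, bias), backward)


def masked_max(x: Tensor, mask: np.ndarray) -> Tensor:
    """Max over the time axis of (B, T, n), ignoring positions where mask==0."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any(axis=1).all():
        raise ValueError("masked_max: every sequence needs at least one valid position")
    neg = np.where(mask[:, :, None], x.data, -np.inf)
    arg = neg.argmax(axis=1)  # (B, n)
    B, _, n = x.data.shape
    bi = np.arange(B)[:, None]
    ni = np.arange(n)[None, :]
    data = x.data[bi, arg, ni]

    def backward(g: np.ndarray) -> None:
        if x.requires_grad:
            full = np.zeros_like(x.data)
            np.add.at(full, (bi, arg, ni), g)
            x._accumulate(full)

    return Tensor._make(data, (x,), backward)


def cross_entropy_logits(logits: Tensor, targets: np.ndarray,
                         mask: Optional[np.ndarray] = None) -> Tensor:
    """Mean token-level cross entropy over unmasked positions.

    ``logits`` is (..., V); ``targets`` holds integer class ids of matching
    leading shape; ``mask`` (same shape as targets) selects the positions that
    count.  Fused softmax + NLL for numerical stability.
    """
    targets = np.asarray(targets)
    if mask is None:
        mask = np.ones(targets.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    count = int(mask.sum())
    if count == 0:
        raise ValueError("cross_entropy_logits: mask selects no positions")
    shifted = logits.data - logits.data.max(axis=-1, keepdims=True)
    expS = np.exp(shifted)
    Z = expS.sum(axis=-1)
    logZ = np.log(Z)
    picked = np.take_along_axis(shifted, targets[..., None], axis=-1)[..., 0]
    nll = (logZ - picked) * mask
    data = np.array(nll.sum() / count)

    def backward(g: np.ndarray) -> None:
        if logits.requires_grad:
            dl = expS / Z[..., None]
            dl[(*np.indices(targets.shape), targets)] -= 1.0
            dl *= mask[..., None] * (float(g) / count)
            logits._accumulate(dl)

    return Tensor._make(data, (logits,), backward)


def parameters_of(objs: Iterable) -> list[Tensor]:
    """Flatten the ``parameters()`` of a heterogeneous collection."""
    out: list[Tensor] = []
    for obj in objs:
        if isinstance(obj, Tensor):
            out.append(obj)
        else:
            out.extend(obj.parameters())
    return out
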