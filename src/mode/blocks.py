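"""SPS-backed primitive layers shared by all three task models.

Every weight matrix here is either a module-local dense parameter or a
*templated* weight regenerated from the global template on each forward pass
(see :mod:`mode.sps`).  Templated weights are restricted to shapes the
template can carve: n x n linears and n x n x k convolution kernels.
Embedding tables, vocabulary projections and scalar heads stay dense and
module-local — their vocabulary-sized dimension exceeds the template's
spatial extent under realistic settings.

Conventions: sequences are (batch, time, features); masks are (batch, time)
with 1 on real tokens and 0 on padding.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .sps import Template, bind_module, sps_generate, xavier_uniform

_NEG_INF = -1e9


# ---------------------------------------------------------------------------
# weight sources


class DenseWeight:
    """A plain trainable weight tensor."""

    def __init__(self, shape: Tuple[int, ...], rng: np.random.Generator,
                 fan_in: Optional[int] = None, fan_out: Optional[int] = None):
        fan_in = fan_in if fan_in is not None else shape[0]
        fan_out = fan_out if fan_out is not None else shape[-1]
        self.tensor = Tensor(xavier_uniform(shape, fan_in, fan_out, rng),
                             requires_grad=True)

    def get(self) -> Tensor:
        return self.tensor

    def parameters(self) -> List[Tensor]:
        return [self.tensor]

    def n_dense_params(self) -> int:
        return int(self.tensor.data.size)


class TemplatedWeight:
    """A weight carved out of the global template by a per-module SPS kernel."""

    def __init__(self, module_id: str, kind: str, target_shape: Tuple[int, ...],
                 template: Template, rng: np.random.Generator):
        self.template = template
        self.kind = kind
        self.binding = bind_module(module_id, kind, target_shape, template, rng)
        self._cached: Optional[Tensor] = None

    def _finish(self, raw: Tensor) -> Tensor:
        """Bias, activation and layout from the raw correlation output."""
        k = self.binding.kernel
        w = raw + k.bias.reshape(-1, 1, 1)
        w = {"identity": lambda t: t, "tanh": lambda t: t.tanh(),
             "sigmoid": lambda t: t.sigmoid()}[k.activation](w)
        if self.kind == "linear":
            return w[0]                      # (n, m)
        # conv: generated (k, n_in, n_out) -> (n_in, n_out, k)
        return w.swapaxes(0, 1).swapaxes(1, 2)

    def get(self) -> Tensor:
        if self._cached is not None:
            return self._cached
        w = sps_generate(self.template, self.binding.kernel)
        if self.kind == "linear":
            return w[0]
        return w.swapaxes(0, 1).swapaxes(1, 2)

    def parameters(self) -> List[Tensor]:
        k = self.binding.kernel
        return [k.values, k.bias]

    def n_dense_params(self) -> int:
        return int(np.prod(self.binding.target_shape))


def generate_group(template: Template, weights: List["TemplatedWeight"]) -> None:
    """Regenerate many templated weights with one batched correlation.

    All kernels that share a spatial extent are concatenated along the
    output-slice axis and carved from the template in a single valid
    cross-correlation (one FFT of the template instead of one per module).
    The generated tensors are cached on each weight for the current forward
    pass; the next call overwrites them, so every training step still sees
    freshly generated parameters.
    """
    if not np.isfinite(template.values.data).all():
        raise FloatingPointError("template contains non-finite entries")
    groups: Dict[Tuple[int, int], List[TemplatedWeight]] = {}
    for w in weights:
        _, _, kh, kw = w.binding.kernel.values.shape
        groups.setdefault((kh, kw), []).append(w)
    for ws in groups.values():
        big = ad.concat([w.binding.kernel.values for w in ws], axis=1)
        raw = ad.sps_correlate(template.values, big)
        lo = 0
        for w in ws:
            p0 = w.binding.kernel.values.shape[1]
            w._cached = w._finish(raw[lo:lo + p0])
            lo += p0


def _weight(module_id: str, kind: str, target_shape, template, rng):
    if template is not None:
        return TemplatedWeight(module_id, kind, target_shape, template, rng)
    if kind == "linear":
        shape = target_shape
    else:
        n, _, k = target_shape
        shape = (n, n, k)
    return DenseWeight(shape, rng, fan_in=shape[0], fan_out=shape[1])


# ---------------------------------------------------------------------------
# layers


class Linear:
    """Position-wise affine map X W + b with an optionally templated W."""

    def __init__(self, module_id: str, n_in: int, n_out: int,
                 rng: np.random.Generator, template: Optional[Template] = None,
                 bias: bool = True):
        self.n_in, self.n_out = n_in, n_out
        self.weight = _weight(module_id, "linear", (n_in, n_out), template, rng)
        self.bias = Tensor(np.zeros(n_out), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[-1] != self.n_in:
            raise ValueError(f"expected last dim {self.n_in}, got {x.shape[-1]}")
        out = x @ self.weight.get()
        if self.bias is not None:
            out = out + self.bias
        return out

    __call__ = forward

    def parameters(self) -> List[Tensor]:
        ps = list(self.weight.parameters())
        if self.bias is not None:
            ps.append(self.bias)
        return ps

    def templated_weights(self) -> List[TemplatedWeight]:
        return [self.weight] if isinstance(self.weight, TemplatedWeight) else []


class Conv1D:
    """Same-padded temporal convolution with equal in/out channels."""

    def __init__(self, module_id: str, channels: int, width: int,
                 rng: np.random.Generator, template: Optional[Template] = None):
        self.channels, self.width = channels, width
        self.weight = _weight(module_id, "conv1d", (channels, channels, width),
                              template, rng)
        self.bias = Tensor(np.zeros(channels), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[-1] != self.channels:
            raise ValueError(f"expected {self.channels} channels, got {x.shape[-1]}")
        return ad.conv1d_same(x, self.weight.get(), self.bias)

    __call__ = forward

    def parameters(self) -> List[Tensor]:
        return list(self.weight.parameters()) + [self.bias]

    def templated_weights(self) -> List[TemplatedWeight]:
        return [self.weight] if isinstance(self.weight, TemplatedWeight) else []


@dataclass
class LSTMState:
    h: Tensor
    c: Tensor


class LSTMCellParams:
    """Eight n x n weight matrices (two linears per gate) plus gate biases.

    Gate order throughout is (f, d, i, o): forget, candidate, input, output.
    """

    GATES = ("f", "d", "i", "o")

    def __init__(self, prefix: str, n: int, rng: np.random.Generator,
                 template: Optional[Template] = None):
        self.n = n
        self.W = {g: _weight(f"{prefix}.W_{g}", "linear", (n, n), template, rng)
                  for g in self.GATES}
        self.U = {g: _weight(f"{prefix}.U_{g}", "linear", (n, n), template, rng)
                  for g in self.GATES}
        self.b = {g: Tensor(np.zeros(n), requires_grad=True) for g in self.GATES}

    def materialize(self) -> Tuple[Tensor, Tensor, Tensor]:
        """Concatenate per-gate weights into (n, 4n) blocks for one matmul."""
        W = ad.concat([self.W[g].get() for g in self.GATES], axis=1)
        U = ad.concat([self.U[g].get() for g in self.GATES], axis=1)
        b = ad.concat([self.b[g] for g in self.GATES], axis=0)
        return W, U, b

    def parameters(self) -> List[Tensor]:
        ps: List[Tensor] = []
        for g in self.GATES:
            ps += self.W[g].parameters() + self.U[g].parameters() + [self.b[g]]
        return ps

    def templated_weights(self) -> List[TemplatedWeight]:
        ws = [self.W[g] for g in self.GATES] + [self.U[g] for g in self.GATES]
        return [w for w in ws if isinstance(w, TemplatedWeight)]


def _lstm_fused(gx: Tensor, h: Tensor, c: Tensor, U: Tensor,
                m: Optional[np.ndarray] = None) -> Tensor:
    """One fused LSTM update returning stacked (2, B, n) = (h_new, c_new).

    A single graph node with a hand-written adjoint keeps the per-timestep
    op count (and Python overhead) low.  ``m`` is an optional (B, 1) update
    mask: rows with 0 keep their previous state (padding positions).
    """
    n = c.data.shape[-1]
    g = gx.data + h.data @ U.data
    sig = lambda z: 1.0 / (1.0 + np.exp(-z))
    f = sig(g[..., 0 * n:1 * n])
    d = np.tanh(g[..., 1 * n:2 * n])
    i = sig(g[..., 2 * n:3 * n])
    o = sig(g[..., 3 * n:4 * n])
    c_new = c.data * f + d * i
    tc = np.tanh(c_new)
    h_new = o * tc
    if m is not None:
        keep = 1.0 - m
        h_out = m * h_new + keep * h.data
        c_out = m * c_new + keep * c.data
    else:
        h_out = h_new
        c_out = c_new
    data = np.stack([h_out, c_out])

    def backward(grad: np.ndarray) -> None:
        dh_out, dc_out = grad[0], grad[1]
        if m is not None:
            keep = 1.0 - m
            dh_new, dc_new = dh_out * m, dc_out * m
        else:
            dh_new, dc_new = dh_out, dc_out
        do = dh_new * tc
        dc_tot = dc_new + dh_new * o * (1.0 - tc * tc)
        dg = np.concatenate([
            dc_tot * c.data * f * (1.0 - f),
            dc_tot * i * (1.0 - d * d),
            dc_tot * d * i * (1.0 - i),
            do * o * (1.0 - o)], axis=-1)
        if gx.requires_grad:
            gx._accumulate(dg)
        if h.requires_grad:
            dh = dg @ U.data.T
            if m is not None:
                dh += dh_out * keep
            h._accumulate(dh)
        if c.requires_grad:
            dc = dc_tot * f
            if m is not None:
                dc += dc_out * keep
            c._accumulate(dc)
        if U.requires_grad:
            U._accumulate(h.data.T @ dg)

    return Tensor._make(data, (gx, h, c, U), backward)


def _gate_step(state: LSTMState, gx: Tensor, U: Tensor, n: int,
               m: Optional[np.ndarray] = None) -> LSTMState:
    """Gate math given the precomputed input contribution gx = x W + b."""
    out = _lstm_fused(gx, state.h, state.c, U, m)
    return LSTMState(h=out[0], c=out[1])


def lstm_cell_step(state: LSTMState, x_t: Tensor, params: LSTMCellParams,
                   mats: Optional[Tuple[Tensor, Tensor, Tensor]] = None) -> LSTMState:
    """One recurrence step: c_t = c * f + d * i, h_t = o * tanh(c_t).

    Gates f/i/o pass through the logistic function, the candidate d through
    tanh.  ``mats`` lets a sequence loop reuse weights materialized once.
    """
    if not (np.isfinite(state.h.data).all() and np.isfinite(state.c.data).all()):
        raise FloatingPointError("non-finite LSTM state")
    W, U, b = mats if mats is not None else params.materialize()
    return _gate_step(state, x_t @ W + b, U, params.n)


class LSTMLayer:
    """Unidirectional LSTM over a padded batch, with masked state updates."""

    def __init__(self, prefix: str, n: int, rng: np.random.Generator,
                 template: Optional[Template] = None):
        self.n = n
        self.params = LSTMCellParams(prefix, n, rng, template)

    def forward(self, x: Tensor, mask: Optional[np.ndarray] = None,
                init: Optional[LSTMState] = None
                ) -> Tuple[Tensor, LSTMState]:
        """Return (outputs (B,T,n), final state).

        Padded positions (mask 0) freeze the state, so the final state is the
        state at each sequence's true last token.
        """
        B, T, _ = x.shape
        if T == 0:
            raise ValueError("empty sequence")
        W, U, b = self.params.materialize()
        gx = x @ W + b  # input contribution for every step in one matmul
        if init is None:
            zeros = Tensor(np.zeros((B, self.n)))
            state = LSTMState(h=zeros, c=zeros)
        else:
            state = init
        outs: List[Tensor] = []
        for t in range(T):
            m = mask[:, t:t + 1].astype(float) if mask is not None else None
            state = _gate_step(state, gx[:, t, :], U, self.n, m)
            outs.append(state.h)
        return ad.stack(outs, axis=1), state

    __call__ = forward

    def parameters(self) -> List[Tensor]:
        return self.params.parameters()

    def templated_weights(self) -> List[TemplatedWeight]:
        return self.params.templated_weights()


def reverse_padded(ids_or_x, mask: np.ndarray):
    """Reverse each row of a right-padded batch within its true length."""
    mask = np.asarray(mask, dtype=bool)
    B, T = mask.shape
    lengths = mask.sum(axis=1)
    idx = np.arange(T)[None, :].repeat(B, axis=0)
    valid = idx < lengths[:, None]
    rev = np.where(valid, lengths[:, None] - 1 - idx, idx)
    bi = np.arange(B)[:, None]
    if isinstance(ids_or_x, Tensor):
        return ids_or_x[bi, rev]
    return np.asarray(ids_or_x)[bi, rev]


class BiLSTM:
    """One bidirectional layer: channel concat of forward and reversed passes."""

    def __init__(self, prefix: str, n: int, rng: np.random.Generator,
                 template: Optional[Template] = None):
        self.fwd = LSTMLayer(f"{prefix}.fwd", n, rng, template)
        self.bwd = LSTMLayer(f"{prefix}.bwd", n, rng, template)

    def forward(self, x: Tensor, mask: np.ndarray
                ) -> Tuple[Tensor, LSTMState, LSTMState]:
        out_f, st_f = self.fwd(x, mask)
        x_rev = reverse_padded(x, mask)
        out_b_rev, st_b = self.bwd(x_rev, mask)
        out_b = reverse_padded(out_b_rev, mask)
        return ad.concat([out_f, out_b], axis=-1), st_f, st_b

    __call__ = forward

    def parameters(self) -> List[Tensor]:
        return self.fwd.parameters() + self.bwd.parameters()

    def templated_weights(self) -> List[TemplatedWeight]:
        return self.fwd.templated_weights() + self.bwd.templated_weights()


def attention(Q: Tensor, K: Tensor, V: Tensor, causal: bool = False,
              key_mask: Optional[np.ndarray] = None,
              return_weights: bool = False):
    """Scaled dot-product attention: softmax(Q K^T / sqrt(n)) V.

    Single head.  ``causal`` masks future positions (query i attends only to
    keys j <= i); ``key_mask`` (B, Tk) removes padded keys.  Rows of the
    attention matrix sum to one.
    """
    n = Q.shape[-1]
    if K.shape[-1] != n:
        raise ValueError("Q and K feature dims differ")
    if K.shape[-2] != V.shape[-2]:
        raise ValueError("K and V lengths differ")
    scores = (Q @ K.swapaxes(-1, -2)) * (1.0 / np.sqrt(n))
    Tq, Tk = scores.shape[-2], scores.shape[-1]
    add = np.zeros((Tq, Tk))
    if causal:
        add = np.where(np.arange(Tk)[None, :] > np.arange(Tq)[:, None], _NEG_INF, 0.0)
    if key_mask is not None:
        km = np.where(np.asarray(key_mask, dtype=bool), 0.0, _NEG_INF)
        add = add[None, :, :] + km[:, None, :]
    scores = scores + Tensor(add)
    weights = ad.softmax(scores, axis=-1)
    out = weights @ V
    if return_weights:
        return out, weights
    return out


class AttentionBlock:
    """Q/K/V projections (templated n x n linears) around scaled dot-product."""

    def __init__(self, prefix: str, n: int, rng: np.random.Generator,
                 template: Optional[Template] = None):
        self.n = n
        self.Wq = Linear(f"{prefix}.W_q", n, n, rng, template, bias=False)
        self.Wk = Linear(f"{prefix}.W_k", n, n, rng, template, bias=False)
        self.Wv = Linear(f"{prefix}.W_v", n, n, rng, template, bias=False)

    def forward(self, x_q: Tensor, x_kv: Tensor, causal: bool = False,
                key_mask: Optional[np.ndarray] = None) -> Tensor:
        return attention(self.Wq(x_q), self.Wk(x_kv), self.Wv(x_kv),
                         causal=causal, key_mask=key_mask)

    __call__ = forward

    def parameters(self) -> List[Tensor]:
        return self.Wq.parameters() + self.Wk.parameters() + self.Wv.parameters()

    def templated_weights(self) -> List[TemplatedWeight]:
        return (self.Wq.templated_weights() + self.Wk.templated_weights()
                + self.Wv.templated_weights())


class FFN:
    """Position-wise feed-forward: linear(n->n), ReLU, linear(n->n)."""

    def __init__(self, prefix: str, n: int, rng: np.random.Generator,
                 template: Optional[Template] = None, dropout: float = 0.0):
        self.inner = Linear(f"{prefix}.ffn1", n, n, rng, template)
        self.outer = Linear(f"{prefix}.ffn2", n, n, rng, template)
        self.dropout = dropout

    def forward(self, x: Tensor, rng: Optional[np.random.Generator] = None,
                training: bool = False) -> Tensor:
        h = self.inner(x).relu()
        h = apply_dropout(h, self.dropout, rng, training)
        return self.outer(h)

    __call__ = forward

    def parameters(self) -> List[Tensor]:
        return self.inner.parameters() + self.outer.parameters()

    def templated_weights(self) -> List[TemplatedWeight]:
        return self.inner.templated_weights() + self.outer.templated_weights()


class Embedding:
    """Dense, module-local token embedding table (not templated)."""

    def __init__(self, vocab: int, n: int, rng: np.random.Generator):
        self.table = Tensor(xavier_uniform((vocab, n), vocab, n, rng),
                            requires_grad=True)
        self.vocab = vocab

    def forward(self, ids: np.ndarray) -> Tensor:
        ids = np.asarray(ids)
        if ids.size and ids.max() >= self.vocab:
            raise ValueError(f"token id {ids.max()} >= vocab size {self.vocab}")
        return ad.embedding_lookup(self.table, ids)

    __call__ = forward

    def parameters(self) -> List[Tensor]:
        return [self.table]


def sinusoidal_positions(T: int, n: int) -> np.ndarray:
    """Classic fixed sine/cosine position encodings, shape (T, n)."""
    pos = np.arange(T)[:, None]
    dim = np.arange(n)[None, :]
    angles = pos / np.power(10000.0, (2 * (dim // 2)) / n)
    enc = np.zeros((T, n))
    enc[:, 0::2] = np.sin(angles[:, 0::2])
    enc[:, 1::2] = np.cos(angles[:, 1::2])
    return enc


def apply_dropout(x: Tensor, rate: float, rng: Optional[np.random.Generator],
                  training: bool) -> Tensor:
    """Inverted dropout; identity when not training or rate is zero."""
    if not training or rate <= 0.0 or rng is None:
        return x
    keep = 1.0 - rate
    mask = (rng.random(x.shape) < keep) / keep
    return x * Tensor(mask)
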