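"""The three task networks assembled from SPS-backed blocks.

* :class:`SummaryModel` — BiLSTM encoder / LSTM decoder that writes the
  Impression for a Finding (auxiliary task 1).
* :class:`SeverityModel` — two 1-D convolution stacks over Finding and
  Impression, pooled into a scalar severity regression (auxiliary task 2).
* :class:`ATRModel` — encoder–decoder Transformer generating the Treatment
  recommendation from Finding + Impression (the main task).

When constructed with a :class:`~mode.sps.Template`, every internal n x n
weight and n x n x k convolution kernel is carved out of that template, so
the three models physically share one parameter store.  Embeddings, the
vocabulary projections and the scalar severity head stay module-local.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .blocks import (FFN, AttentionBlock, BiLSTM, Conv1D, Embedding, Linear,
                     LSTMLayer, LSTMState, apply_dropout, generate_group,
                     sinusoidal_positions)
from .sps import Template

PAD_ID, UNK_ID, START_ID, END_ID = 0, 1, 2, 3


@dataclass
class ModelConfig:
    """Shared structural hyper-parameters for all three task models."""

    n: int = 64                 # hidden size; must fit the template spatially
    L: int = 2                  # layer count per encoder/decoder stack
    vocab: int = 1000
    conv_width: int = 3
    max_decode_len: int = 80
    flags_enabled: bool = True
    templated: bool = True
    dropout: float = 0.1

    def validate(self, template: Optional[Template]) -> None:
        if self.L < 1:
            raise ValueError("layer count must be >= 1")
        if template is not None:
            _, r, c = template.shape
            if self.n > min(r, c):
                raise ValueError(
                    f"hidden size {self.n} exceeds template spatial extent "
                    f"({r}, {c})")


class _ModelBase:
    def __init__(self, cfg: ModelConfig, template: Optional[Template], seed: int):
        cfg.validate(template)
        self.cfg = cfg
        self.template = template if cfg.templated else None
        self.rng = np.random.default_rng(seed)
        self.drop_rng = np.random.default_rng(seed + 10_000)
        self._modules: List = []

    def _reg(self, module):
        self._modules.append(module)
        return module

    def parameters(self) -> List[Tensor]:
        """All module-local and kernel parameters (template excluded)."""
        ps: List[Tensor] = []
        for m in self._modules:
            if isinstance(m, Tensor):
                ps.append(m)
            else:
                ps.extend(m.parameters())
        return ps

    def templated_weights(self) -> List:
        ws: List = []
        for m in self._modules:
            getter = getattr(m, "templated_weights", None)
            if getter is not None:
                ws.extend(getter())
        return ws

    def regenerate(self) -> None:
        """Carve all of this model's shared weights from the template in one
        batched correlation; called at the start of every forward pass."""
        if self.template is not None:
            ws = self.templated_weights()
            if ws:
                generate_group(self.template, ws)

    def local_bias_sizes(self) -> dict:
        """module_id -> local bias length, for parameter accounting."""
        out = {}
        for m in self._modules:
            if isinstance(m, Linear) and m.bias is not None and \
                    hasattr(m.weight, "binding"):
                out[m.weight.binding.module_id] = m.n_out
            if isinstance(m, Conv1D) and hasattr(m.weight, "binding"):
                out[m.weight.binding.module_id] = m.channels
        return out


def _mask_of(ids: np.ndarray) -> np.ndarray:
    return np.asarray(ids) != PAD_ID


class SummaryModel(_ModelBase):
    """Finding -> Impression BiLSTM encoder–decoder.

    The encoder is a stack of L bidirectional LSTM layers; its 2n-channel
    output is folded back to n between layers by a pair of n x n linears
    (one per direction, summed) so every shared weight stays n x n.  The
    decoder is an L-layer LSTM initialized from the encoder's final states
    and driven by teacher forcing; an FFN plus a dense vocabulary projection
    produce per-position logits.
    """

    task = "summary"

    def __init__(self, cfg: ModelConfig, template: Optional[Template] = None,
                 seed: int = 0):
        super().__init__(cfg, template, seed)
        t, rng, n = self.template, self.rng, cfg.n
        self.embed = self._reg(Embedding(cfg.vocab, n, rng))
        self.enc_layers = [self._reg(BiLSTM(f"sum.enc{l}", n, rng, t))
                           for l in range(cfg.L)]
        self.enc_proj = [(self._reg(Linear(f"sum.encproj{l}.f", n, n, rng, t)),
                          self._reg(Linear(f"sum.encproj{l}.b", n, n, rng, t)))
                         for l in range(cfg.L - 1)]
        self.bridge_h = (self._reg(Linear("sum.bridge.hf", n, n, rng, t)),
                         self._reg(Linear("sum.bridge.hb", n, n, rng, t)))
        self.bridge_c = (self._reg(Linear("sum.bridge.cf", n, n, rng, t)),
                         self._reg(Linear("sum.bridge.cb", n, n, rng, t)))
        self.dec_layers = [self._reg(LSTMLayer(f"sum.dec{l}", n, rng, t))
                           for l in range(cfg.L)]
        self.out_ffn = self._reg(FFN("sum.out", n, rng, t, dropout=cfg.dropout))
        self.proj = self._reg(Linear("sum.vocab", n, cfg.vocab, rng, None))

    def encode(self, F: np.ndarray, training: bool = False
               ) -> Tuple[Tensor, LSTMState]:
        self.regenerate()
        mask = _mask_of(F)
        if not mask.any(axis=1).all():
            raise ValueError("empty Finding sequence")
        # sqrt(n) scaling compensates the vocabulary-sized fan-in of the
        # Xavier-initialized table; without it LSTM inputs are ~0.05-scale
        x = self.embed(F) * np.sqrt(self.cfg.n)
        x = apply_dropout(x, self.cfg.dropout, self.drop_rng, training)
        st_f = st_b = None
        z = None
        for l, layer in enumerate(self.enc_layers):
            z, st_f, st_b = layer(x, mask)
            if l < len(self.enc_layers) - 1:
                pf, pb = self.enc_proj[l]
                n = self.cfg.n
                x = (pf(z[..., :n]) + pb(z[..., n:])).tanh()
        h0 = (self.bridge_h[0](st_f.h) + self.bridge_h[1](st_b.h)).tanh()
        c0 = (self.bridge_c[0](st_f.c) + self.bridge_c[1](st_b.c)).tanh()
        return z, LSTMState(h=h0, c=c0)

    def forward(self, F: np.ndarray, teacher: np.ndarray,
                training: bool = False) -> Tensor:
        """Teacher-forced logits, shape (B, len(teacher), vocab)."""
        _, init = self.encode(F, training)
        y = self.embed(teacher) * np.sqrt(self.cfg.n)
        y = apply_dropout(y, self.cfg.dropout, self.drop_rng, training)
        for l, layer in enumerate(self.dec_layers):
            y, _ = layer(y, mask=None, init=init if l == 0 else None)
        h = self.out_ffn(y, self.drop_rng, training)
        return self.proj(h)

    __call__ = forward


class SeverityModel(_ModelBase):
    """(Finding, Impression) -> scalar severity regression.

    Separate L-layer convolution stacks (ReLU between layers) encode each
    field; the streams are concatenated along time, max-pooled over the
    valid positions, and mapped to one scalar by an FFN and a dense head.
    Padding positions are zeroed before the convolutions and excluded from
    the pool, so the output is invariant to pad-token content.
    """

    task = "severity"

    def __init__(self, cfg: ModelConfig, template: Optional[Template] = None,
                 seed: int = 1):
        super().__init__(cfg, template, seed)
        t, rng, n, k = self.template, self.rng, cfg.n, cfg.conv_width
        self.embed = self._reg(Embedding(cfg.vocab, n, rng))
        self.conv_f = [self._reg(Conv1D(f"sev.f{l}", n, k, rng, t))
                       for l in range(cfg.L)]
        self.conv_i = [self._reg(Conv1D(f"sev.i{l}", n, k, rng, t))
                       for l in range(cfg.L)]
        self.ffn = self._reg(FFN("sev.out", n, rng, t, dropout=cfg.dropout))
        self.head = self._reg(Linear("sev.head", n, 1, rng, None))

    def _stream(self, ids: np.ndarray, convs, training: bool) -> Tensor:
        mask = _mask_of(ids)
        if not mask.any(axis=1).all():
            raise ValueError("empty input sequence")
        x = self.embed(ids) * np.sqrt(self.cfg.n)
        x = x * Tensor(mask[:, :, None].astype(float))
        x = apply_dropout(x, self.cfg.dropout, self.drop_rng, training)
        for l, conv in enumerate(convs):
            x = conv(x)
            if l < len(convs) - 1:
                x = x.relu()
            x = x * Tensor(mask[:, :, None].astype(float))
        return x

    def forward(self, F: np.ndarray, I: np.ndarray,
                training: bool = False) -> Tensor:
        """Severity scores on the [0, 1] scale, shape (B,)."""
        self.regenerate()
        zf = self._stream(F, self.conv_f, training)
        zi = self._stream(I, self.conv_i, training)
        z = ad.concat([zf, zi], axis=1)
        mask = np.concatenate([_mask_of(F), _mask_of(I)], axis=1)
        pooled = ad.masked_max(z, mask)
        h = self.ffn(pooled, self.drop_rng, training)
        s = self.head(h)
        return s.reshape(s.shape[0])

    __call__ = forward


class ATRModel(_ModelBase):
    """(Finding, Impression) -> Treatment encoder–decoder Transformer.

    One L-block self-attention + FFN encoder per source field; the encoded
    sequences are concatenated along time into the memory.  The decoder
    alternates masked self-attention, FFN, cross-attention to the memory and
    FFN, followed by a dense vocabulary projection.  Single-head attention
    and sinusoidal position encodings; each attention and FFN sub-block is
    wrapped in an additive residual path (without them the uniform-attention
    initialization is a saddle point the optimizer cannot leave), but there
    is no layer normalization.
    """

    task = "atr"

    def __init__(self, cfg: ModelConfig, template: Optional[Template] = None,
                 seed: int = 2):
        super().__init__(cfg, template, seed)
        t, rng, n = self.template, self.rng, cfg.n
        self.embed = self._reg(Embedding(cfg.vocab, n, rng))
        self.enc_f = [(self._reg(AttentionBlock(f"atr.encF{l}.attn", n, rng, t)),
                       self._reg(FFN(f"atr.encF{l}.ffn", n, rng, t, cfg.dropout)))
                      for l in range(cfg.L)]
        self.enc_i = [(self._reg(AttentionBlock(f"atr.encI{l}.attn", n, rng, t)),
                       self._reg(FFN(f"atr.encI{l}.ffn", n, rng, t, cfg.dropout)))
                      for l in range(cfg.L)]
        self.dec = [(self._reg(AttentionBlock(f"atr.dec{l}.self", n, rng, t)),
                     self._reg(FFN(f"atr.dec{l}.ffn1", n, rng, t, cfg.dropout)),
                     self._reg(AttentionBlock(f"atr.dec{l}.cross", n, rng, t)),
                     self._reg(FFN(f"atr.dec{l}.ffn2", n, rng, t, cfg.dropout)))
                    for l in range(cfg.L)]
        self.proj = self._reg(Linear("atr.vocab", n, cfg.vocab, rng, None))

    def _embed_pos(self, ids: np.ndarray, training: bool) -> Tensor:
        # sqrt(n) scaling keeps token identity from being drowned by the
        # O(1)-amplitude position encodings
        x = self.embed(ids) * np.sqrt(self.cfg.n)
        x = x + Tensor(sinusoidal_positions(ids.shape[1], self.cfg.n))
        return apply_dropout(x, self.cfg.dropout, self.drop_rng, training)

    def _encode_stream(self, ids: np.ndarray, stack, training: bool) -> Tensor:
        mask = _mask_of(ids)
        if not mask.any(axis=1).all():
            raise ValueError("empty input sequence")
        x = self._embed_pos(ids, training)
        for attn, ffn in stack:
            x = x + attn(x, x, key_mask=mask)
            x = x + ffn(x, self.drop_rng, training)
        return x

    def encode(self, F: np.ndarray, I: np.ndarray, training: bool = False
               ) -> Tuple[Tensor, np.ndarray]:
        """Memory of shape (B, |F| + |I|, n) plus its padding mask."""
        self.regenerate()
        zf = self._encode_stream(F, self.enc_f, training)
        zi = self._encode_stream(I, self.enc_i, training)
        memory = ad.concat([zf, zi], axis=1)
        mem_mask = np.concatenate([_mask_of(F), _mask_of(I)], axis=1)
        return memory, mem_mask

    def forward(self, F: np.ndarray, I: np.ndarray, teacher: np.ndarray,
                training: bool = False) -> Tensor:
        """Teacher-forced logits, shape (B, len(teacher), vocab)."""
        memory, mem_mask = self.encode(F, I, training)
        y = self._embed_pos(teacher, training)
        for self_attn, ffn1, cross, ffn2 in self.dec:
            y = y + self_attn(y, y, causal=True)
            y = y + ffn1(y, self.drop_rng, training)
            y = y + cross(y, memory, key_mask=mem_mask)
            y = y + ffn2(y, self.drop_rng, training)
        return self.proj(y)

    __call__ = forward


def greedy_decode(model, sources: Sequence[np.ndarray], max_len: int) -> List[int]:
    """Deterministic greedy decoding for a single record.

    ``sources`` is (F,) for the summary model or (F, I) for the ATR model,
    each a 1-D id array.  Starts from <start> when flags are enabled (a pad
    placeholder otherwise), appends the argmax token each step, stops at
    <end> or ``max_len``, and returns the sequence with flags stripped.
    """
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    flags = model.cfg.flags_enabled
    prefix = [START_ID if flags else PAD_ID]
    out: List[int] = []
    srcs = [np.asarray(s)[None, :] for s in sources]
    for _ in range(max_len):
        teacher = np.asarray(prefix)[None, :]
        logits = model.forward(*srcs, teacher, training=False)
        nxt = int(np.argmax(logits.data[0, -1]))
        if flags and nxt == END_ID:
            break
        out.append(nxt)
        prefix.append(nxt)
    return [t for t in out if t not in (PAD_ID, START_ID, END_ID)]
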