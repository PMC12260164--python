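"""LSTM baseline over the same encoded sequences as the transformer.

Single-layer LSTM with the usual input/forget/cell/output gating; padded
positions carry the previous hidden state forward so trailing padding
never changes the final representation. The masked-mean pooled hidden
states are concatenated with the static covariates and fed to the same
two-layer head as the transformer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Parameter, Tensor
from .transformer import _init_linear


@dataclass
class LSTMConfig:
    embed_dim: int = 32
    hidden_dim: int = 32
    dropout: float = 0.0
    max_len: int = 256
    lr: float = 1e-3
    batch_size: int = 128
    epochs: int = 30
    patience: int = 3
    seed: int = 0
    val_fraction: float = 0.1
    head_hidden: int = 32
    time_bucket_days: int = 10
    n_time_buckets: int = 18
    dtype: str = "float32"


class LSTMNet:
    def __init__(self, vocab_size: int, n_static: int, cfg: LSTMConfig):
        self.cfg = cfg
        dtype = np.dtype(cfg.dtype)
        rng = np.random.default_rng(cfg.seed)
        d, h = cfg.embed_dim, cfg.hidden_dim
        self.tok_emb = Parameter(rng.normal(0, 0.02, (vocab_size, d)).astype(dtype))
        self.time_emb = Parameter(
            rng.normal(0, 0.02, (cfg.n_time_buckets, d)).astype(dtype)
        )
        self.w_gates, self.b_gates = _init_linear(rng, d + h, 4 * h, dtype)
        # positive initial forget bias helps remembering early events
        self.b_gates.data[h:2 * h] = 1.0
        self.h1_w, self.h1_b = _init_linear(rng, h + n_static, cfg.head_hidden, dtype)
        self.h2_w, self.h2_b = _init_linear(rng, cfg.head_hidden, 1, dtype)

    def parameters(self):
        return [self.tok_emb, self.time_emb, self.w_gates, self.b_gates,
                self.h1_w, self.h1_b, self.h2_w, self.h2_b]

    def forward(self, ids, days, mask, statics, train=False, rng=None) -> Tensor:
        cfg = self.cfg
        dtype = self.tok_emb.data.dtype
        B, L = ids.shape
        h_dim = cfg.hidden_dim
        statics = np.asarray(statics, dtype=dtype)
        buckets = np.clip(days // cfg.time_bucket_days, 0, cfg.n_time_buckets - 1)
        x = ad.add(ad.embedding(self.tok_emb, ids),
                   ad.embedding(self.time_emb, buckets))
        x = ad.dropout(x, cfg.dropout, rng, train)

        h = Tensor(np.zeros((B, h_dim), dtype=dtype), requires_grad=False)
        c = Tensor(np.zeros((B, h_dim), dtype=dtype), requires_grad=False)
        mf = mask.astype(dtype)
        for t in range(L):
            xt = ad.slice_axis1(x, t)
            gates = ad.linear(ad.concat([xt, h], axis=-1), self.w_gates, self.b_gates)
            gi = _cols(gates, 0, h_dim)
            gf = _cols(gates, h_dim, 2 * h_dim)
            gc = _cols(gates, 2 * h_dim, 3 * h_dim)
            go = _cols(gates, 3 * h_dim, 4 * h_dim)
            c_new = ad.add(ad.mul(ad.sigmoid(gf), c),
                           ad.mul(ad.sigmoid(gi), ad.tanh(gc)))
            h_new = ad.mul(ad.sigmoid(go), ad.tanh(c_new))
            m = mf[:, t][:, None]
            c = ad.add(ad.mul(c_new, m), ad.mul(c, 1.0 - m))
            h = ad.add(ad.mul(h_new, m), ad.mul(h, 1.0 - m))

        z = ad.concat([h, Tensor(statics, requires_grad=False)], axis=-1)
        hh = ad.relu(ad.linear(z, self.h1_w, self.h1_b))
        return ad.linear(hh, self.h2_w, self.h2_b)

    def state(self):
        return [p.data.copy() for p in self.parameters()]

    def load_state(self, state):
        for p, s in zip(self.parameters(), state):
            p.data[...] = s


def _cols(a: Tensor, lo: int, hi: int) -> Tensor:
    out = Tensor(a.data[:, lo:hi], (a,))

    def bwd(g):
        full = np.zeros_like(a.data)
        full[:, lo:hi] = g
        ad._accum(a, full)

    out.bwd = bwd
    return out
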