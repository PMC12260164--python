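"""Transformer encoder for 180-day medical-code sequences.

Architecture: token embedding + learned positional embedding + learned
embedding of the bucketed day offset -> pre-norm multi-head self-attention
encoder stack with a key padding mask -> masked mean pooling over real
tokens -> concatenation with the static covariate vector -> two-layer
feed-forward head -> logistic output. Trained by minimising binary
cross-entropy with Adam and early stopping on a validation split.

Patients with no lookback events pool to a zero sequence vector, so their
prediction depends only on the static covariates, and appended padding
positions never influence a prediction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Parameter, Tensor


@dataclass
class TransformerConfig:
    embed_dim: int = 64
    n_heads: int = 4
    n_layers: int = 2
    ff_dim: int = 128
    dropout: float = 0.1
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

    def __post_init__(self) -> None:
        if self.embed_dim % self.n_heads:
            raise ValueError("embed_dim must be divisible by n_heads")
        for name in ("embed_dim", "n_heads", "n_layers", "ff_dim", "max_len",
                     "batch_size", "epochs", "head_hidden"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def _init_linear(rng, n_in, n_out, dtype):
    lim = np.sqrt(6.0 / (n_in + n_out))
    w = Parameter(rng.uniform(-lim, lim, (n_in, n_out)).astype(dtype))
    b = Parameter(np.zeros(n_out, dtype=dtype))
    return w, b


class TransformerNet:
    """Parameters + forward pass; see module docstring for the contract."""

    def __init__(self, vocab_size: int, n_static: int, cfg: TransformerConfig):
        self.cfg = cfg
        self.vocab_size = vocab_size
        self.n_static = n_static
        dtype = np.dtype(cfg.dtype)
        rng = np.random.default_rng(cfg.seed)
        d = cfg.embed_dim
        self.tok_emb = Parameter(rng.normal(0, 0.02, (vocab_size, d)).astype(dtype))
        self.pos_emb = Parameter(rng.normal(0, 0.02, (cfg.max_len, d)).astype(dtype))
        self.time_emb = Parameter(
            rng.normal(0, 0.02, (cfg.n_time_buckets, d)).astype(dtype)
        )
        self.layers = []
        for _ in range(cfg.n_layers):
            lyr = {}
            for nm in ("wq", "wk", "wv", "wo"):
                lyr[nm], lyr[nm + "_b"] = _init_linear(rng, d, d, dtype)
            lyr["ln1_g"] = Parameter(np.ones(d, dtype=dtype))
            lyr["ln1_b"] = Parameter(np.zeros(d, dtype=dtype))
            lyr["w1"], lyr["w1_b"] = _init_linear(rng, d, cfg.ff_dim, dtype)
            lyr["w2"], lyr["w2_b"] = _init_linear(rng, cfg.ff_dim, d, dtype)
            lyr["ln2_g"] = Parameter(np.ones(d, dtype=dtype))
            lyr["ln2_b"] = Parameter(np.zeros(d, dtype=dtype))
            self.layers.append(lyr)
        self.lnf_g = Parameter(np.ones(d, dtype=dtype))
        self.lnf_b = Parameter(np.zeros(d, dtype=dtype))
        self.h1_w, self.h1_b = _init_linear(rng, d + n_static, cfg.head_hidden, dtype)
        self.h2_w, self.h2_b = _init_linear(rng, cfg.head_hidden, 1, dtype)

    def parameters(self) -> list[Parameter]:
        ps = [self.tok_emb, self.pos_emb, self.time_emb,
              self.lnf_g, self.lnf_b, self.h1_w, self.h1_b, self.h2_w, self.h2_b]
        for lyr in self.layers:
            ps.extend(lyr.values())
        return ps

    def forward(self, ids, days, mask, statics, train=False, rng=None) -> Tensor:
        """Return logits (B, 1) for a batch of encoded patients."""
        cfg = self.cfg
        dtype = self.tok_emb.data.dtype
        B, L = ids.shape
        d, H = cfg.embed_dim, cfg.n_heads
        dh = d // H
        statics = np.asarray(statics, dtype=dtype)

        buckets = np.clip(days // cfg.time_bucket_days, 0, cfg.n_time_buckets - 1)
        x = ad.add(
            ad.add(ad.embedding(self.tok_emb, ids),
                   ad.embedding(self.pos_emb, np.arange(L))),
            ad.embedding(self.time_emb, buckets),
        )
        x = ad.dropout(x, cfg.dropout, rng, train)

        # additive key padding mask: (B, 1, 1, L)
        neg = np.where(mask, 0.0, -1e9).astype(dtype)[:, None, None, :]

        for lyr in self.layers:
            h = ad.layer_norm(x, lyr["ln1_g"], lyr["ln1_b"])
            q = ad.linear(h, lyr["wq"], lyr["wq_b"])
            k = ad.linear(h, lyr["wk"], lyr["wk_b"])
            v = ad.linear(h, lyr["wv"], lyr["wv_b"])
            # (B, L, d) -> (B, H, L, dh)
            q = ad.transpose(ad.reshape(q, (B, L, H, dh)), (0, 2, 1, 3))
            k = ad.transpose(ad.reshape(k, (B, L, H, dh)), (0, 2, 1, 3))
            v = ad.transpose(ad.reshape(v, (B, L, H, dh)), (0, 2, 1, 3))
            scores = ad.scale(ad.matmul(q, ad.transpose(k, (0, 1, 3, 2))),
                              1.0 / np.sqrt(dh))
            attn = ad.softmax(scores, additive_mask=neg)
            ctx = ad.matmul(attn, v)
            ctx = ad.reshape(ad.transpose(ctx, (0, 2, 1, 3)), (B, L, d))
            ctx = ad.linear(ctx, lyr["wo"], lyr["wo_b"])
            x = ad.add(x, ad.dropout(ctx, cfg.dropout, rng, train))
            h2 = ad.layer_norm(x, lyr["ln2_g"], lyr["ln2_b"])
            f = ad.linear(ad.relu(ad.linear(h2, lyr["w1"], lyr["w1_b"])),
                          lyr["w2"], lyr["w2_b"])
            x = ad.add(x, ad.dropout(f, cfg.dropout, rng, train))

        x = ad.layer_norm(x, self.lnf_g, self.lnf_b)
        pooled = ad.masked_mean(x, mask)
        z = ad.concat([pooled, Tensor(statics, requires_grad=False)], axis=-1)
        h = ad.relu(ad.linear(z, self.h1_w, self.h1_b))
        return ad.linear(h, self.h2_w, self.h2_b)

    # -- persistence of the best validation state ---------------------------
    def state(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state(self, state: list[np.ndarray]) -> None:
        for p, s in zip(self.parameters(), state):
            p.data[...] = s


@dataclass
class TrainingLog:
    epochs: list[int] = field(default_factory=list)
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)


def train_network(
    net: TransformerNet | "object",
    ids: np.ndarray,
    days: np.ndarray,
    mask: np.ndarray,
    statics: np.ndarray,
    y: np.ndarray,
    cfg,
) -> TrainingLog:
    """Minibatch Adam training with early stopping on a validation split.

    Works for any network exposing forward/parameters/state/load_state
    (shared by the transformer and the LSTM baseline).
    """
    y = np.asarray(y).astype(int).ravel()
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    n = len(y)
    rng = np.random.default_rng(cfg.seed + 1)
    order = rng.permutation(n)
    n_val = max(1, int(round(cfg.val_fraction * n))) if n >= 20 else 0
    val_idx, tr_idx = order[:n_val], order[n_val:]

    opt = ad.Adam(net.parameters(), lr=cfg.lr)
    drop_rng = np.random.default_rng(cfg.seed + 2)
    log = TrainingLog()
    best_val = np.inf
    best_state = net.state()
    bad = 0
    for epoch in range(cfg.epochs):
        perm = rng.permutation(len(tr_idx))
        losses = []
        for start in range(0, len(tr_idx), cfg.batch_size):
            b = tr_idx[perm[start:start + cfg.batch_size]]
            opt.zero_grad()
            logits = net.forward(ids[b], days[b], mask[b], statics[b],
                                 train=True, rng=drop_rng)
            loss = ad.bce_with_logits(logits, y[b])
            if not np.isfinite(loss.data):
                raise FloatingPointError("non-finite training loss")
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        tr_loss = float(np.mean(losses))
        if n_val:
            vl = net.forward(ids[val_idx], days[val_idx], mask[val_idx],
                             statics[val_idx])
            val_loss = float(ad.bce_with_logits(vl, y[val_idx]).data)
        else:
            val_loss = tr_loss
        log.epochs.append(epoch)
        log.train_loss.append(tr_loss)
        log.val_loss.append(val_loss)
        if val_loss < best_val - 1e-5:
            best_val = val_loss
            best_state = net.state()
            bad = 0
        else:
            bad += 1
            if bad >= cfg.patience:
                break
    net.load_state(best_state)
    return log


def predict_proba_batched(net, ids, days, mask, statics, batch_size=1024):
    out = []
    for start in range(0, len(ids), batch_size):
        sl = slice(start, start + batch_size)
        logits = net.forward(ids[sl], days[sl], mask[sl], statics[sl])
        out.append(ad._sigmoid_np(logits.data).ravel())
    if not out:
        return np.zeros(0)
    return np.concatenate(out).astype(float)
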