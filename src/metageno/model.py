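"""Sequence backbones over the 22 chromosome tokens, six disease heads and
the multi-task training loop.

The backbone consumes the chromosome-aware representation Z (B, 22, d) and
produces a trunk vector per sample; six independent linear heads with a
sigmoid give one probability per disease. The loss is a task-weighted sum
of per-task mean binary cross-entropies (computed from logits for
stability). Everything runs on the in-repo autodiff engine, so training is
deterministic for a fixed seed in single-threaded numpy.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .autodiff import Adam, Parameter, Tensor, concat
from .chromembed import ChromosomeEmbedding
from .genodata import DISEASES

BACKBONE_KINDS = ("transformer", "lstm", "gru", "cnn", "tcn")


@dataclass
class BackboneConfig:
    kind: str = "transformer"
    depth: int = 1
    width: int = 16
    heads: int = 2
    dropout: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.kind not in BACKBONE_KINDS:
            raise ValueError(f"unknown backbone kind {self.kind!r}")


@dataclass
class TaskPredictions:
    probs: np.ndarray   # (n, 6) in (0, 1), DISEASES column order
    logits: np.ndarray  # (n, 6)


def _linear(rng, n_in, n_out):
    s = np.sqrt(2.0 / (n_in + n_out))
    return Parameter(rng.normal(0, s, size=(n_in, n_out))), Parameter(np.zeros(n_out))


class _LayerNorm:
    def __init__(self, dim):
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc / ((var + 1e-6) ** 0.5) * self.gamma + self.beta

    def params(self):
        return [self.gamma, self.beta]


class _TransformerBlock:
    """Pre-norm block: multi-head self-attention + 2-layer MLP, residuals."""

    def __init__(self, rng, width, heads):
        if width % heads:
            raise ValueError("width must be divisible by heads")
        self.width, self.heads = width, heads
        self.ln1, self.ln2 = _LayerNorm(width), _LayerNorm(width)
        self.Wq, self.bq = _linear(rng, width, width)
        self.Wk, self.bk = _linear(rng, width, width)
        self.Wv, self.bv = _linear(rng, width, width)
        self.Wo, self.bo = _linear(rng, width, width)
        self.W1, self.b1 = _linear(rng, width, 2 * width)
        self.W2, self.b2 = _linear(rng, 2 * width, width)
        self.last_alpha: Optional[np.ndarray] = None

    def __call__(self, x: Tensor) -> Tensor:
        B, T, W = x.data.shape
        h, dk = self.heads, W // self.heads
        y = self.ln1(x)
        q = (y @ self.Wq + self.bq).reshape(B, T, h, dk).swapaxes(1, 2)
        k = (y @ self.Wk + self.bk).reshape(B, T, h, dk).swapaxes(1, 2)
        v = (y @ self.Wv + self.bv).reshape(B, T, h, dk).swapaxes(1, 2)
        alpha = ((q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(dk))).softmax(axis=-1)
        self.last_alpha = alpha.data
        att = (alpha @ v).swapaxes(1, 2).reshape(B, T, W)
        x = x + att @ self.Wo + self.bo
        y = self.ln2(x)
        return x + (y @ self.W1 + self.b1).relu() @ self.W2 + self.b2

    def params(self):
        return (self.ln1.params() + self.ln2.params()
                + [self.Wq, self.bq, self.Wk, self.bk, self.Wv, self.bv,
                   self.Wo, self.bo, self.W1, self.b1, self.W2, self.b2])


class _RecurrentBackbone:
    """LSTM or GRU over the 22 chromosome tokens; final hidden state."""

    def __init__(self, rng, d, cfg: BackboneConfig):
        self.kind = cfg.kind
        self.width = cfg.width
        g = 4 if cfg.kind == "lstm" else 3
        self.Wx, _ = _linear(rng, d, g * cfg.width)
        self.Wh, _ = _linear(rng, cfg.width, g * cfg.width)
        self.b = Parameter(np.zeros(g * cfg.width))

    def __call__(self, z: Tensor) -> Tensor:
        B, T, _ = z.data.shape
        W = self.width
        h = Tensor(np.zeros((B, W)))
        c = Tensor(np.zeros((B, W)))
        for t in range(T):
            xt = z[:, t, :]
            gates = xt @ self.Wx + h @ self.Wh + self.b
            if self.kind == "lstm":
                i = gates[:, 0:W].sigmoid()
                f = gates[:, W:2 * W].sigmoid()
                g = gates[:, 2 * W:3 * W].tanh()
                o = gates[:, 3 * W:4 * W].sigmoid()
                c = f * c + i * g
                h = o * c.tanh()
            else:  # gru
                r = gates[:, 0:W].sigmoid()
                u = gates[:, W:2 * W].sigmoid()
                n = (xt @ self.Wx[:, 2 * W:3 * W]
                     + r * (h @ self.Wh[:, 2 * W:3 * W]) + self.b[2 * W:3 * W]).tanh()
                h = (1.0 - u) * n + u * h
        return h

    def params(self):
        return [self.Wx, self.Wh, self.b]


class _ConvBackbone:
    """1-D convolutions over the token axis (dilated + causal for tcn)."""

    def __init__(self, rng, d, cfg: BackboneConfig):
        self.kind = cfg.kind
        self.width = cfg.width
        self.ksize = 3
        self.layers = []
        n_in = d
        depth = max(cfg.depth, 1)
        for layer in range(depth):
            dilation = 2 ** layer if cfg.kind == "tcn" else 1
            Wk = [_linear(rng, n_in, cfg.width)[0] for _ in range(self.ksize)]
            b = Parameter(np.zeros(cfg.width))
            self.layers.append((Wk, b, dilation))
            n_in = cfg.width

    def __call__(self, z: Tensor) -> Tensor:
        x = z
        for Wk, b, dilation in self.layers:
            B, T, _ = x.data.shape
            pad_total = dilation * (self.ksize - 1)
            if self.kind == "tcn":  # causal: pad left only
                before, after = pad_total, 0
            else:
                before = pad_total // 2
                after = pad_total - before
            zeros_b = Tensor(np.zeros((B, before, x.data.shape[2])))
            zeros_a = Tensor(np.zeros((B, after, x.data.shape[2])))
            xp = concat([zeros_b, x, zeros_a], axis=1)
            acc = None
            for kk, W in enumerate(Wk):
                sl = xp[:, kk * dilation: kk * dilation + T, :] @ W
                acc = sl if acc is None else acc + sl
            x = (acc + b).relu()
        return x.mean(axis=1)

    def params(self):
        out = []
        for Wk, b, _ in self.layers:
            out.extend(Wk)
            out.append(b)
        return out


class Backbone:
    """Dispatch wrapper producing a trunk vector from Z (B, 22, d)."""

    def __init__(self, d: int, cfg: BackboneConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        self.blocks: list = []
        self._proj = None
        if cfg.kind == "transformer":
            if cfg.depth > 0:
                self._proj = _linear(rng, d, cfg.width)
                self.blocks = [_TransformerBlock(rng, cfg.width, cfg.heads)
                               for _ in range(cfg.depth)]
                self.trunk_dim = cfg.width
            else:
                self.trunk_dim = d  # identity blocks: mean of Z rows
        elif cfg.kind in ("lstm", "gru"):
            self.net = _RecurrentBackbone(rng, d, cfg)
            self.trunk_dim = cfg.width
        else:
            self.net = _ConvBackbone(rng, d, cfg)
            self.trunk_dim = cfg.width

    def __call__(self, Z: Tensor) -> Tensor:
        if self.cfg.kind == "transformer":
            if self.cfg.depth == 0:
                return Z.mean(axis=-2)
            W, b = self._proj
            x = Z @ W + b
            for blk in self.blocks:
                x = blk(x)
            return x.mean(axis=1)
        return self.net(Z)

    def params(self):
        if self.cfg.kind == "transformer":
            if self.cfg.depth == 0:
                return []
            W, b = self._proj
            out = [W, b]
            for blk in self.blocks:
                out.extend(blk.params())
            return out
        return self.net.params()


class TaskHeads:
    """Six independent linear heads (one column per disease) + sigmoid."""

    def __init__(self, trunk_dim: int, seed: int = 0):
        rng = np.random.default_rng(seed + 101)
        self.W, self.b = _linear(rng, trunk_dim, len(DISEASES))

    def logits(self, trunk: Tensor) -> Tensor:
        return trunk @ self.W + self.b

    def params(self):
        return [self.W, self.b]


def predict_tasks(trunk: Tensor, heads: TaskHeads) -> TaskPredictions:
    logits = heads.logits(trunk)
    z = np.clip(logits.data, -30.0, 30.0)
    return TaskPredictions(probs=1.0 / (1.0 + np.exp(-z)), logits=logits.data)


def multitask_loss(logits: Tensor, labels: np.ndarray,
                   task_weights: Sequence = (1.0,) * 6) -> Tensor:
    """Weighted sum over tasks of mean binary cross-entropy.

    Uses the stable logit form softplus(z) - y*z; weights of zero mask a
    task entirely (single-task mode).
    """
    labels = np.asarray(labels, dtype=float)
    if not np.isin(labels, (0.0, 1.0)).all():
        raise ValueError("labels must be binary")
    w = np.asarray(task_weights, dtype=float)
    if np.any(w < 0) or not np.any(w > 0):
        raise ValueError("task weights must be >= 0 and not all zero")
    bce = logits.softplus() - logits * labels          # (n, 6)
    return (bce.mean(axis=0) * w).sum()


@dataclass
class TrainConfig:
    lr: float = 1e-3
    batch_size: int = 256
    epochs: int = 30
    seed: int = 0
    task_weights: Sequence = (1.0,) * 6
    weight_decay: float = 0.0

    def single_task(self) -> "TrainConfig":
        return replace(self, task_weights=(1.0, 0.0, 0.0, 0.0, 0.0, 0.0))


def sinusoidal_positions(n_tokens: int, d: int) -> np.ndarray:
    """Fixed sine/cosine positional encodings (no learned parameters)."""
    pos = np.arange(n_tokens)[:, None]
    i = np.arange(d)[None, :]
    angle = pos / np.power(10000.0, (2 * (i // 2)) / d)
    pe = np.where(i % 2 == 0, np.sin(angle), np.cos(angle))
    return pe


class MetaGenoModel:
    """Embedding layer + backbone + heads, end to end.

    In chromosome_wise mode the backbone consumes the 22 x d representation;
    the ablation modes hand it one token per SNP plus fixed sinusoidal
    positional encodings (SNP identity without learned parameters).
    """

    def __init__(self, groups, d: int = 8, V: int = 4,
                 mode: str = "chromosome_wise",
                 backbone: Optional[BackboneConfig] = None,
                 seed: int = 0, positional: bool = True):
        backbone = backbone or BackboneConfig(seed=seed)
        self.embedding = ChromosomeEmbedding(groups, d=d, V=V, mode=mode,
                                             seed=seed, positional=positional)
        self.backbone = Backbone(d, backbone)
        self.heads = TaskHeads(self.backbone.trunk_dim, seed=seed)
        self.mode = mode
        if mode != "chromosome_wise":
            n_tokens = int(sum(g.m for g in self.embedding.groups))
            self._pe = sinusoidal_positions(n_tokens, d)
        else:
            self._pe = None

    def params(self) -> list:
        return (self.embedding.trainable() + self.backbone.params()
                + self.heads.params())

    def forward_logits(self, states: np.ndarray,
                       keep_attention: bool = False) -> Tensor:
        Z = self.embedding.forward(states, keep_attention=keep_attention)
        if self._pe is not None:
            Z = Z + Tensor(self._pe)
        trunk = self.backbone(Z)
        return self.heads.logits(trunk)

    def predict(self, states: np.ndarray, batch_size: int = 512) -> TaskPredictions:
        from .autodiff import no_grad
        probs, logits = [], []
        for lo in range(0, len(states), batch_size):
            with no_grad():
                lg = self.forward_logits(states[lo:lo + batch_size]).data
            z = np.clip(lg, -30.0, 30.0)
            probs.append(1.0 / (1.0 + np.exp(-z)))
            logits.append(lg)
        return TaskPredictions(np.concatenate(probs), np.concatenate(logits))


def fit(model: MetaGenoModel, states: np.ndarray, labels: np.ndarray,
        cfg: TrainConfig) -> list:
    """Mini-batch Adam training; returns the per-epoch mean loss history."""
    rng = np.random.default_rng(cfg.seed)
    params = model.params()
    opt = Adam(params, lr=cfg.lr, weight_decay=cfg.weight_decay)
    n = len(states)
    history = []
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for lo in range(0, n, cfg.batch_size):
            idx = order[lo:lo + cfg.batch_size]
            logits = model.forward_logits(states[idx])
            loss = multitask_loss(logits, labels[idx], cfg.task_weights)
            loss.backward()
            opt.step()
            losses.append(loss.item())
        history.append(float(np.mean(losses)))
    return history
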