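"""The seizure-prediction classifier: time-distributed pseudo-3D CNN ->
bidirectional ConvLSTM3D -> squeeze-excitation channel attention -> dense head.

Architecture summary for the reference configuration (N=3 features on a
4 x 7 electrode grid, T=2 time steps of 3 s):

* Pseudo-3D stack: six convolutions alternating spatial (1x3x3) and
  feature-axis (3x1x1) kernels with channel ladder 64-64-128-128-256-256,
  ReLU throughout, batch normalization after every pair. Spatial dimensions
  are preserved (same padding), so each step maps (3,4,7,1) -> (3,4,7,256).
  The stack is applied to both time steps with shared weights
  (time-distributed), implemented by folding time into the batch axis.
* Bi-ConvLSTM3D: 256 hidden channels per direction, 1x1x1 gate kernels,
  biased gates, no peephole by default. The two final hidden states are
  concatenated on the channel axis (512 channels): 1,050,624 parameters.
* Attention: squeeze-excitation over the 512 channels with reduction 8
  (bottleneck 64): 66,112 parameters.
* Head: global average pool -> dense 64 (ReLU) -> dropout -> softmax(2).

Training is Adam on cross-entropy; everything is seeded and deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .nn import (Adam, BatchNorm, Conv3D, ConvLSTM3DCell, Dense, Dropout,
                 GlobalAvgPool, ReLU, SEAttention3D, softmax)

logger = logging.getLogger(__name__)

SPATIAL_KERNEL = (1, 3, 3)
FEATURE_KERNEL = (3, 1, 1)


def _default_kernels():
    return (SPATIAL_KERNEL, FEATURE_KERNEL) * 3


@dataclass(frozen=True)
class ModelConfig:
    """Architecture + training hyperparameters (defaults = reference model)."""

    n_features: int = 3
    grid_h: int = 4
    grid_w: int = 7
    time_steps: int = 2
    p3d_channels: tuple[int, ...] = (64, 64, 128, 128, 256, 256)
    p3d_kernels: tuple[tuple[int, int, int], ...] = field(
        default_factory=_default_kernels
    )
    bn_after_pairs: bool = True
    convlstm_hidden: int = 256
    convlstm_kernel: tuple[int, int, int] = (1, 1, 1)
    peephole: bool = False
    attention_channels: int = 512
    attention_reduction: int = 8
    head_hidden: int = 64
    n_classes: int = 2
    dropout: float = 0.25
    optimizer: str = "adam"
    learning_rate: float = 1e-3
    batch_size: int = 32
    epochs: int = 30
    val_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "p3d_channels", tuple(self.p3d_channels))
        object.__setattr__(
            self, "p3d_kernels", tuple(tuple(k) for k in self.p3d_kernels)
        )
        if len(self.p3d_channels) != len(self.p3d_kernels):
            raise ValueError("p3d_channels and p3d_kernels must align")
        if self.attention_channels != 2 * self.convlstm_hidden:
            raise ValueError("attention_channels must equal 2 * convlstm_hidden")
        if self.attention_channels % self.attention_reduction:
            raise ValueError("attention_reduction must divide attention_channels")

    @property
    def grid(self) -> tuple[int, int, int]:
        return (self.n_features, self.grid_h, self.grid_w)

    @classmethod
    def reference(cls, **overrides) -> "ModelConfig":
        return cls(**overrides)

    @classmethod
    def reduced(cls, **overrides) -> "ModelConfig":
        """Desk-scale configuration for experiments and cross-validation."""
        base = dict(
            p3d_channels=(8, 8, 16, 16, 32, 32),
            convlstm_hidden=16,
            attention_channels=32,
            attention_reduction=4,
            head_hidden=16,
            epochs=12,
        )
        base.update(overrides)
        return cls(**base)


def count_parameters(config: ModelConfig) -> dict[str, int]:
    """Exact trainable-parameter counts per component, from shapes alone."""
    p3d = 0
    cin = 1
    for i, (cout, kernel) in enumerate(zip(config.p3d_channels, config.p3d_kernels)):
        p3d += int(np.prod(kernel)) * cin * cout + cout
        if config.bn_after_pairs and i % 2 == 1:
            p3d += 2 * cout  # gamma + beta
        cin = cout
    k_prod = int(np.prod(config.convlstm_kernel))
    h = config.convlstm_hidden
    per_dir = k_prod * cin * 4 * h + k_prod * h * 4 * h + 4 * h
    if config.peephole:
        per_dir += 3 * h
    bi = 2 * per_dir
    c_att = config.attention_channels
    hidden = c_att // config.attention_reduction
    att = c_att * hidden + hidden + hidden * c_att + c_att
    head = (c_att * config.head_hidden + config.head_hidden
            + config.head_hidden * config.n_classes + config.n_classes)
    return {"p3d": p3d, "bi_convlstm3d": bi, "attention3d": att, "head": head,
            "total": p3d + bi + att + head}


class SeizurePredictor:
    """End-to-end model with explicit forward/backward passes."""

    def __init__(self, config: ModelConfig):
        self.config = config
        self.rng = np.random.default_rng(config.seed)
        rng = self.rng
        self.p3d_layers = []
        cin = 1
        for i, (cout, kernel) in enumerate(zip(config.p3d_channels,
                                               config.p3d_kernels)):
            self.p3d_layers.append(Conv3D(cin, cout, kernel, rng))
            self.p3d_layers.append(ReLU())
            if config.bn_after_pairs and i % 2 == 1:
                self.p3d_layers.append(BatchNorm(cout))
            cin = cout
        self.cell_fwd = ConvLSTM3DCell(cin, config.convlstm_hidden,
                                       config.convlstm_kernel, rng,
                                       peephole=config.peephole)
        self.cell_bwd = ConvLSTM3DCell(cin, config.convlstm_hidden,
                                       config.convlstm_kernel, rng,
                                       peephole=config.peephole)
        self.attention = SEAttention3D(config.attention_channels,
                                       config.attention_reduction, rng)
        self.pool = GlobalAvgPool()
        self.fc1 = Dense(config.attention_channels, config.head_hidden, rng)
        self.relu_head = ReLU()
        self.drop = Dropout(config.dropout, rng)
        self.fc2 = Dense(config.head_hidden, config.n_classes, rng)

    # -- plumbing ---------------------------------------------------------
    def params(self):
        p = []
        for layer in self.p3d_layers:
            p += layer.params()
        p += self.cell_fwd.params() + self.cell_bwd.params()
        p += self.attention.params() + self.fc1.params() + self.fc2.params()
        return p

    def n_parameters(self) -> int:
        return sum(p.size for p in self.params())

    # -- forward ----------------------------------------------------------
    def _p3d_forward(self, x, training):
        caches = []
        for layer in self.p3d_layers:
            x, c = layer.forward(x, training)
            caches.append(c)
        return x, caches

    def _p3d_backward(self, dout, caches):
        for layer, c in zip(reversed(self.p3d_layers), reversed(caches)):
            dout = layer.backward(dout, c)
        return dout

    def _bilstm_forward(self, seq, training):
        """seq: (B, T, N, H, W, C) -> (B, N, H, W, 2*hidden), caches."""
        b, t = seq.shape[:2]
        grid = seq.shape[2:5]
        caches_f, caches_b = [], []
        h, c = self.cell_fwd.init_state(b, grid)
        for ti in range(t):
            h, c, _, cache = self.cell_fwd.step(seq[:, ti], h, c, training)
            caches_f.append(cache)
        h_fwd = h
        h, c = self.cell_bwd.init_state(b, grid)
        for ti in reversed(range(t)):
            h, c, _, cache = self.cell_bwd.step(seq[:, ti], h, c, training)
            caches_b.append(cache)  # stored in processing order (t = T..1)
        h_bwd = h
        out = np.concatenate([h_fwd, h_bwd], axis=-1)
        return out, (caches_f, caches_b, seq.shape)

    def _bilstm_backward(self, dout, cache):
        caches_f, caches_b, seq_shape = cache
        hd = self.config.convlstm_hidden
        t = seq_shape[1]
        dseq = np.zeros(seq_shape)
        # forward direction: gradient enters at the final step only
        dh = dout[..., :hd]
        dc = np.zeros_like(dh)
        for ti in reversed(range(t)):
            dx, dh, dc = self.cell_fwd.step_backward(dh, dc, caches_f[ti])
            dseq[:, ti] += dx
        # backward direction processed t = T-1 .. 0; its "final" state saw t=0
        dh = dout[..., hd:]
        dc = np.zeros_like(dh)
        for k in reversed(range(t)):
            ti = t - 1 - k  # cache k was built from step index t-1-k
            dx, dh, dc = self.cell_bwd.step_backward(dh, dc, caches_b[k])
            dseq[:, ti] += dx
        return dseq

    def forward(self, x, training=False):
        """x: (B, T, N, H, W, 1) -> logits (B, n_classes), cache."""
        cfg = self.config
        b, t = x.shape[:2]
        if x.shape[2:] != (*cfg.grid, 1):
            raise ValueError(
                f"input shape {x.shape[2:]} does not match configured grid "
                f"{(*cfg.grid, 1)}"
            )
        folded = x.reshape(b * t, *cfg.grid, 1)
        feat, p3d_cache = self._p3d_forward(folded, training)
        seq = feat.reshape(b, t, *feat.shape[1:])
        lstm_out, lstm_cache = self._bilstm_forward(seq, training)
        att, att_cache = self.attention.forward(lstm_out, training)
        pooled, pool_cache = self.pool.forward(att, training)
        z1, fc1_cache = self.fc1.forward(pooled, training)
        a1, relu_cache = self.relu_head.forward(z1, training)
        d1, drop_cache = self.drop.forward(a1, training)
        logits, fc2_cache = self.fc2.forward(d1, training)
        cache = (p3d_cache, lstm_cache, att_cache, pool_cache, fc1_cache,
                 relu_cache, drop_cache, fc2_cache, (b, t))
        return logits, cache

    def backward(self, dlogits, cache):
        (p3d_cache, lstm_cache, att_cache, pool_cache, fc1_cache, relu_cache,
         drop_cache, fc2_cache, (b, t)) = cache
        d = self.fc2.backward(dlogits, fc2_cache)
        d = self.drop.backward(d, drop_cache)
        d = self.relu_head.backward(d, relu_cache)
        d = self.fc1.backward(d, fc1_cache)
        d = self.pool.backward(d, pool_cache)
        d = self.attention.backward(d, att_cache)
        dseq = self._bilstm_backward(d, lstm_cache)
        dfold = dseq.reshape(b * t, *dseq.shape[2:])
        self._p3d_backward(dfold, p3d_cache)

    # -- inference --------------------------------------------------------
    def predict_proba(self, x) -> np.ndarray:
        logits, _ = self.forward(np.asarray(x, dtype=np.float64), training=False)
        return softmax(logits)

    def predict(self, x) -> np.ndarray:
        return self.predict_proba(x).argmax(axis=1)

    # -- training ---------------------------------------------------------
    def loss_and_grad(self, x, y, training=True):
        logits, cache = self.forward(x, training)
        probs = softmax(logits)
        n = x.shape[0]
        eps = 1e-12
        loss = -np.log(probs[np.arange(n), y] + eps).mean()
        dlogits = probs.copy()
        dlogits[np.arange(n), y] -= 1.0
        dlogits /= n
        return loss, dlogits, cache, probs

    def evaluate(self, x, y):
        probs = self.predict_proba(x)
        n = x.shape[0]
        loss = -np.log(probs[np.arange(n), y] + 1e-12).mean()
        acc = float((probs.argmax(axis=1) == y).mean())
        return loss, acc

    def fit(self, x, y, epochs: int | None = None) -> list[dict]:
        """Train with Adam on cross-entropy; returns the per-epoch history."""
        cfg = self.config
        x = np.asarray(x, dtype=np.float64)
        y = np.asarray(y, dtype=np.int64)
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) < 2:
            raise ValueError("training data must contain both classes")
        if counts.min() < 2:
            raise ValueError("need at least 2 samples per class")
        epochs = cfg.epochs if epochs is None else epochs
        if cfg.optimizer.lower() != "adam":
            raise ValueError(f"unsupported optimizer {cfg.optimizer!r}")
        opt = Adam(self.params(), lr=cfg.learning_rate)

        # stratified validation split, seeded
        val_idx = []
        if cfg.val_fraction > 0:
            for cls in classes:
                cls_idx = np.flatnonzero(y == cls)
                perm = self.rng.permutation(cls_idx)
                n_val = int(round(cfg.val_fraction * len(cls_idx)))
                n_val = min(n_val, len(cls_idx) - 2)
                val_idx.extend(perm[:n_val])
        val_idx = np.sort(np.array(val_idx, dtype=int))
        train_idx = np.setdiff1d(np.arange(len(y)), val_idx)

        history = []
        for epoch in range(epochs):
            order = self.rng.permutation(train_idx)
            losses, hits, seen = [], 0, 0
            for start in range(0, len(order), cfg.batch_size):
                batch = order[start:start + cfg.batch_size]
                opt.zero_grad()
                loss, dlogits, cache, probs = self.loss_and_grad(
                    x[batch], y[batch], training=True
                )
                self.backward(dlogits, cache)
                opt.step()
                losses.append(loss * len(batch))
                hits += int((probs.argmax(axis=1) == y[batch]).sum())
                seen += len(batch)
            entry = {
                "epoch": epoch,
                "train_loss": float(np.sum(losses) / seen),
                "train_acc": hits / seen,
            }
            if len(val_idx):
                vl, va = self.evaluate(x[val_idx], y[val_idx])
                entry["val_loss"], entry["val_acc"] = float(vl), va
            history.append(entry)
            logger.info(
                "epoch %d: train_loss=%.4f train_acc=%.3f%s", epoch,
                entry["train_loss"], entry["train_acc"],
                f" val_acc={entry.get('val_acc', float('nan')):.3f}"
                if len(val_idx) else "",
            )
        return history


# -- functional interface ---------------------------------------------------

def p3d_block_forward(x, model: SeizurePredictor, training: bool = False):
    """Run the pseudo-3D stack on (B, N, H, W, C_in) step tensors."""
    out, _ = model._p3d_forward(np.asarray(x, dtype=np.float64), training)
    return out


def convlstm3d_step(x, state, cell: ConvLSTM3DCell, training: bool = False):
    """One ConvLSTM3D recurrence; returns (h, c, gates)."""
    h_prev, c_prev = state
    h, c, gates, _ = cell.step(np.asarray(x, dtype=np.float64), h_prev, c_prev,
                               training)
    return h, c, gates


def bi_convlstm3d_forward(sequence, cell_fwd: ConvLSTM3DCell,
                          cell_bwd: ConvLSTM3DCell):
    """Sequence (B, T, N, H, W, C) -> concatenated final hidden states."""
    sequence = np.asarray(sequence, dtype=np.float64)
    if sequence.ndim != 6 or sequence.shape[1] < 1:
        raise ValueError("sequence must be (B, T>=1, N, H, W, C)")
    b, t = sequence.shape[:2]
    grid = sequence.shape[2:5]
    h, c = cell_fwd.init_state(b, grid)
    for ti in range(t):
        h, c, _, _ = cell_fwd.step(sequence[:, ti], h, c)
    h_fwd = h
    h, c = cell_bwd.init_state(b, grid)
    for ti in reversed(range(t)):
        h, c, _, _ = cell_bwd.step(sequence[:, ti], h, c)
    return np.concatenate([h_fwd, h], axis=-1)


def se_attention3d(x, attention: SEAttention3D):
    out, _ = attention.forward(np.asarray(x, dtype=np.float64))
    return out


def model_forward(model: SeizurePredictor, x) -> np.ndarray:
    """Class probabilities for (B, T, N, H, W, 1) inputs (inference mode)."""
    return model.predict_proba(x)


def train(x, y, config: ModelConfig) -> tuple[SeizurePredictor, list[dict]]:
    """Build a seeded model, fit it, and return (model, history)."""
    model = SeizurePredictor(config)
    history = model.fit(x, y)
    return model, history
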