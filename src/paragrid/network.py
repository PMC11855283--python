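"""Hybrid 3D-ResNet + transformer binding-score network and training loop.

The architecture follows the published outline: an initial 3D convolution
block, four residual stages of dilated bottleneck blocks ending at a
2048-channel trunk, a 1×1×1 compression layer to 256 channels
(batch-normalized, ReLU), a transformer block with self-attention over
the spatial token sequence, global average pooling, dropout (0.1), and a
fully connected sigmoid head producing one binding score per grid.

Per-stage block counts, strides and dilation rates are not published; the
default here is a ResNet-50-style layout (3/4/6/3 bottlenecks, dilation
increasing in the deeper stages) with 8 attention heads, all overridable
through :class:`ModelConfig`.  A width-reduced configuration
(:meth:`ModelConfig.reduced`) trains on CPU at desk scale.

Training uses binary cross-entropy with Adam, learning rate 1e-4 divided
by 5 every 5 epochs, batch size 64.
"""

from __future__ import annotations

import copy
import dataclasses
import json
from pathlib import Path

import numpy as np

from . import nn
from .nn.layers import _out_dim

__all__ = [
    "ModelConfig",
    "TrainConfig",
    "TrainingHistory",
    "ParatopeNet",
    "build_model",
    "train",
    "predict_scores",
    "learning_rate",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclasses.dataclass
class ModelConfig:
    in_channels: int = 22
    grid_size: int = 41
    stem_channels: int = 64
    stem_kernel: int = 7
    stem_stride: int = 2
    stem_pool: bool = True
    block_counts: tuple[int, ...] = (3, 4, 6, 3)
    stage_channels: tuple[int, ...] = (256, 512, 1024, 2048)
    stage_strides: tuple[int, ...] = (1, 2, 1, 1)
    stage_dilations: tuple[int, ...] = (1, 1, 2, 4)
    bottleneck_ratio: int = 4
    compression_channels: int = 256
    attn_heads: int = 8
    attn_mlp_ratio: int = 2
    dropout: float = 0.1

    def __post_init__(self) -> None:
        n = len(self.block_counts)
        if not (len(self.stage_channels) == len(self.stage_strides)
                == len(self.stage_dilations) == n):
            raise ValueError("stage specs must all have the same length")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.compression_channels >= self.stage_channels[-1]:
            raise ValueError("compression must reduce the trunk width")
        if self.compression_channels % self.attn_heads != 0:
            raise ValueError("compression width must be divisible by attention heads")

    @property
    def trunk_channels(self) -> int:
        return self.stage_channels[-1]

    @classmethod
    def default(cls) -> "ModelConfig":
        return cls()

    @classmethod
    def reduced(cls, grid_size: int = 9) -> "ModelConfig":
        """Width-reduced CPU-scale configuration (same topology)."""
        return cls(
            grid_size=grid_size,
            stem_channels=16,
            stem_kernel=3,
            stem_stride=1,
            stem_pool=False,
            block_counts=(1, 1, 1, 1),
            stage_channels=(32, 64, 128, 256),
            stage_strides=(1, 2, 1, 1),
            stage_dilations=(1, 1, 2, 2),
            compression_channels=32,
            attn_heads=4,
        )

    def spatial_extent(self) -> int:
        """Edge length of the post-trunk activation for this grid size."""
        n = self.grid_size
        n = _out_dim(n, self.stem_kernel, self.stem_stride, self.stem_kernel // 2, 1)
        if self.stem_pool:
            n = _out_dim(n, 3, 2, 1, 1)
        for s in self.stage_strides:
            n = _out_dim(n, 1, s, 0, 1)  # stride applied in the first block's 1x1 path
        return n


@dataclasses.dataclass
class TrainConfig:
    epochs: int = 10
    batch_size: int = 64
    initial_lr: float = 1e-4
    lr_decay_factor: float = 5.0
    lr_decay_every: int = 5
    val_fraction: float = 0.15
    patience: int | None = None
    seed: int = 0


def learning_rate(cfg: TrainConfig, epoch: int) -> float:
    """lr(e) = initial_lr / factor**floor(e / every), 0-based epochs."""
    return cfg.initial_lr / cfg.lr_decay_factor ** (epoch // cfg.lr_decay_every)


class _Bottleneck(nn.Module):
    """1×1 reduce → 3×3×3 (stride/dilation) → 1×1 expand, with shortcut."""

    def __init__(self, cin, cout, mid, stride, dilation, rng):
        self.conv1 = nn.Conv3d(cin, mid, 1, bias=False, rng=rng)
        self.bn1 = nn.BatchNorm3d(mid)
        self.conv2 = nn.Conv3d(mid, mid, 3, stride=stride, dilation=dilation,
                               bias=False, rng=rng)
        self.bn2 = nn.BatchNorm3d(mid)
        self.conv3 = nn.Conv3d(mid, cout, 1, bias=False, rng=rng)
        self.bn3 = nn.BatchNorm3d(cout)
        self.relu1, self.relu2, self.relu_out = nn.ReLU(), nn.ReLU(), nn.ReLU()
        if cin != cout or stride != 1:
            self.down_conv = nn.Conv3d(cin, cout, 1, stride=stride, bias=False, rng=rng)
            self.down_bn = nn.BatchNorm3d(cout)
        else:
            self.down_conv = None

    def params(self):
        out = (self.conv1.params() + self.bn1.params() + self.conv2.params()
               + self.bn2.params() + self.conv3.params() + self.bn3.params())
        if self.down_conv is not None:
            out += self.down_conv.params() + self.down_bn.params()
        return out

    def forward(self, x, training=False):
        y = self.relu1.forward(self.bn1.forward(self.conv1.forward(x, training), training), training)
        y = self.relu2.forward(self.bn2.forward(self.conv2.forward(y, training), training), training)
        y = self.bn3.forward(self.conv3.forward(y, training), training)
        if self.down_conv is not None:
            sc = self.down_bn.forward(self.down_conv.forward(x, training), training)
        else:
            sc = x
        return self.relu_out.forward(y + sc, training)

    def backward(self, dy):
        dsum = self.relu_out.backward(dy)
        dx_main = self.conv1.backward(self.bn1.backward(self.relu1.backward(
            self.conv2.backward(self.bn2.backward(self.relu2.backward(
                self.conv3.backward(self.bn3.backward(dsum))))))))
        if self.down_conv is not None:
            dx_sc = self.down_conv.backward(self.down_bn.backward(dsum))
        else:
            dx_sc = dsum
        return dx_main + dx_sc


class ParatopeNet(nn.Module):
    """Binding-score network: grids in, scores in [0, 1] out.

    ``forward`` takes channels-last grids ``(B, S, S, S, C)`` as produced
    by the featurizer and returns logits; :meth:`predict_proba` applies
    the sigmoid.  Pass ``capture={}`` to record named intermediate
    activations (``"post_compression"``) for probing.
    """

    def __init__(self, cfg: ModelConfig, seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        self.rng = np.random.default_rng(seed + 1)  # dropout stream

        k = cfg.stem_kernel
        stem = [
            nn.Conv3d(cfg.in_channels, cfg.stem_channels, k, stride=cfg.stem_stride,
                      padding=k // 2, bias=False, rng=rng),
            nn.BatchNorm3d(cfg.stem_channels),
            nn.ReLU(),
        ]
        if cfg.stem_pool:
            stem.append(nn.MaxPool3d(3, 2, 1))
        self.stem = nn.Sequential(*stem)

        blocks = []
        cin = cfg.stem_channels
        for nblocks, cout, stride, dil in zip(cfg.block_counts, cfg.stage_channels,
                                              cfg.stage_strides, cfg.stage_dilations):
            mid = cout // cfg.bottleneck_ratio
            for b in range(nblocks):
                blocks.append(_Bottleneck(cin, cout, mid, stride if b == 0 else 1,
                                          dil, rng))
                cin = cout
        self.trunk = nn.Sequential(*blocks)

        self.compression = nn.Sequential(
            nn.Conv3d(cfg.trunk_channels, cfg.compression_channels, 1, bias=False, rng=rng),
            nn.BatchNorm3d(cfg.compression_channels),
            nn.ReLU(),
        )

        self._tokens = self._token_count()
        c = cfg.compression_channels
        self.pos_embed = nn.Parameter(
            (rng.standard_normal((self._tokens, c)) * 0.02).astype(np.float32))
        self.transformer = nn.TransformerBlock(c, cfg.attn_heads, cfg.attn_mlp_ratio, rng=rng)
        self.dropout = nn.Dropout(cfg.dropout, rng=self.rng)
        self.head = nn.Linear(c, 1, rng=rng)

    def _token_count(self) -> int:
        n = self.cfg.spatial_extent()
        self._spatial = (n, n, n)
        return n ** 3

    def params(self):
        return (self.stem.params() + self.trunk.params() + self.compression.params()
                + [self.pos_embed] + self.transformer.params() + self.head.params())

    def _check_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        if x.ndim != 5 or x.shape[-1] != self.cfg.in_channels:
            raise ValueError(
                f"expected grids of shape (B, S, S, S, {self.cfg.in_channels}), "
                f"got {x.shape}")
        return np.ascontiguousarray(x.transpose(0, 4, 1, 2, 3))

    def forward(self, x, training=False, capture: dict | None = None):
        x = self._check_input(x)
        B = x.shape[0]
        z = self.stem.forward(x, training)
        z = self.trunk.forward(z, training)
        z = self.compression.forward(z, training)
        if capture is not None:
            capture["post_compression"] = z
        # flatten the spatial grid into a token sequence
        c = self.cfg.compression_channels
        tokens = z.reshape(B, c, -1).transpose(0, 2, 1)
        tokens = tokens + self.pos_embed.value
        t = self.transformer.forward(tokens, training)
        pooled = t.mean(axis=1)
        if training:
            self._pool_T = t.shape[1]
        pooled = self.dropout.forward(pooled, training)
        logits = self.head.forward(pooled, training)[:, 0]
        return logits

    def backward(self, dlogits):
        dpooled = self.head.backward(dlogits[:, None])
        dpooled = self.dropout.backward(dpooled)
        T = self._pool_T
        dt = np.repeat(dpooled[:, None, :], T, axis=1) / T
        dtok = self.transformer.backward(dt.astype(np.float32))
        self.pos_embed.grad += dtok.sum(axis=0)
        B = dtok.shape[0]
        c = self.cfg.compression_channels
        dz = dtok.transpose(0, 2, 1).reshape(B, c, *self._spatial)
        dz = self.compression.backward(np.ascontiguousarray(dz))
        dz = self.trunk.backward(dz)
        return self.stem.backward(dz)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return nn.sigmoid(self.forward(x, training=False))

    # -- state dict -----------------------------------------------------
    def state_arrays(self) -> dict[str, np.ndarray]:
        out = {}
        for i, p in enumerate(self.params()):
            out[f"p{i}"] = p.value
        for j, bn in enumerate(self._batchnorms()):
            out[f"rm{j}"] = bn.running_mean
            out[f"rv{j}"] = bn.running_var
        return out

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.params()):
            p.value = np.array(arrays[f"p{i}"])
            p.grad = np.zeros_like(p.value)
        for j, bn in enumerate(self._batchnorms()):
            bn.running_mean = np.array(arrays[f"rm{j}"])
            bn.running_var = np.array(arrays[f"rv{j}"])

    def _batchnorms(self):
        found = []

        def visit(m):
            if isinstance(m, nn.BatchNorm3d):
                found.append(m)
            elif isinstance(m, nn.Sequential):
                for sub in m.modules:
                    visit(sub)
            elif isinstance(m, _Bottleneck):
                for sub in (m.bn1, m.bn2, m.bn3):
                    found.append(sub)
                if m.down_conv is not None:
                    found.append(m.down_bn)
        for m in (self.stem, self.trunk, self.compression):
            visit(m)
        return found


def build_model(cfg: ModelConfig | None = None, seed: int = 0) -> ParatopeNet:
    """Construct the binding-score network from a configuration."""
    return ParatopeNet(cfg or ModelConfig.default(), seed=seed)


@dataclasses.dataclass
class TrainingHistory:
    epochs: list[dict]
    best_epoch: int

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("epoch\tlr\ttrain_loss\tval_loss\n")
            for e in self.epochs:
                fh.write(f"{e['epoch']}\t{e['lr']:.8g}\t{e['train_loss']:.6f}\t"
                         f"{e['val_loss']:.6f}\n")


def train(model: ParatopeNet, dataset, cfg: TrainConfig) -> TrainingHistory:
    """Train with BCE/Adam under the stepped learning-rate schedule.

    ``dataset`` needs ``X`` (grids, channels-last) and ``y`` (0/1 labels)
    attributes, or may be a ``(X, y)`` tuple.  A validation split is held
    out; the best-validation-loss weights are restored at the end.
    Deterministic for a fixed seed.
    """
    if isinstance(dataset, tuple):
        X, y = dataset
    else:
        X, y = dataset.X, dataset.y
    X = np.asarray(X, dtype=np.float32)
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("training requires both classes present (balanced-design BCE)")

    rng = np.random.default_rng(cfg.seed)
    model.rng = np.random.default_rng(cfg.seed + 1)
    model.dropout.rng = model.rng
    n = len(X)
    order = rng.permutation(n)
    n_val = max(1, int(round(cfg.val_fraction * n)))
    val_idx, train_idx = order[:n_val], order[n_val:]

    opt = nn.Adam(model.params(), lr=cfg.initial_lr)
    history: list[dict] = []
    best_val = np.inf
    best_state: dict | None = None
    best_epoch = -1
    since_best = 0

    for epoch in range(cfg.epochs):
        lr = learning_rate(cfg, epoch)
        opt.lr = lr
        perm = rng.permutation(train_idx)
        losses = []
        for start in range(0, len(perm), cfg.batch_size):
            idx = perm[start:start + cfg.batch_size]
            logits = model.forward(X[idx], training=True)
            loss, dz = nn.bce_with_logits(logits, y[idx])
            opt.zero_grad()
            model.backward(dz.astype(np.float32))
            opt.step()
            losses.append(loss)
        val_loss = _eval_loss(model, X[val_idx], y[val_idx], cfg.batch_size)
        history.append({
            "epoch": epoch,
            "lr": lr,
            "train_loss": float(np.mean(losses)),
            "val_loss": val_loss,
        })
        if val_loss < best_val:
            best_val = val_loss
            best_state = copy.deepcopy(model.state_arrays())
            best_epoch = epoch
            since_best = 0
        else:
            since_best += 1
            if cfg.patience is not None and since_best > cfg.patience:
                break
    if best_state is not None:
        model.load_state_arrays(best_state)
    return TrainingHistory(epochs=history, best_epoch=best_epoch)


def _eval_loss(model, X, y, batch_size) -> float:
    total, count = 0.0, 0
    for start in range(0, len(X), batch_size):
        logits = model.forward(X[start:start + batch_size], training=False)
        loss, _ = nn.bce_with_logits(logits, y[start:start + batch_size])
        total += loss * len(logits)
        count += len(logits)
    return total / max(count, 1)


def predict_scores(model: ParatopeNet, grids: np.ndarray, batch_size: int = 64) -> np.ndarray:
    """Score a batch of grids in eval mode; order-preserving, in [0, 1]."""
    grids = np.asarray(grids, dtype=np.float32)
    if grids.ndim == 4:
        grids = grids[None]
    out = []
    for start in range(0, len(grids), batch_size):
        out.append(model.predict_proba(grids[start:start + batch_size]))
    return np.concatenate(out) if out else np.empty(0)


def save_checkpoint(model: ParatopeNet, path: str | Path,
                    train_cfg: TrainConfig | None = None,
                    history: TrainingHistory | None = None) -> None:
    meta = {
        "model_config": dataclasses.asdict(model.cfg),
        "train_config": dataclasses.asdict(train_cfg) if train_cfg else None,
        "history": history.epochs if history else None,
    }
    arrays = model.state_arrays()
    np.savez_compressed(path, __meta__=json.dumps(meta), **arrays)


def load_checkpoint(path: str | Path) -> ParatopeNet:
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["__meta__"]))
        mc = meta["model_config"]
        for key in ("block_counts", "stage_channels", "stage_strides", "stage_dilations"):
            mc[key] = tuple(mc[key])
        model = ParatopeNet(ModelConfig(**mc))
        model.load_state_arrays({k: z[k] for k in z.files if k != "__meta__"})
    return model
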