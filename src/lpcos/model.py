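"""The segmentation network: a compact U-Net variant in pure NumPy.

Two departures from the classic U-Net, both aimed at preserving small,
low-contrast structure: every convolution pair carries an identity
shortcut (1x1 projection where the channel count changes), and all
down-sampling is done by 3x3 convolutions with stride 2 — there is no
pooling anywhere.  The decoder up-samples with 2x2 transposed
convolutions, concatenates the encoder skip at each level, and a final
1x1 convolution with a per-pixel two-class softmax yields the vessel
probability.

Training follows a plain regime: pixel-wise categorical cross entropy,
stochastic gradient descent (learning rate 0.01), mini-batches of 32
patches, with the patch set resampled every epoch.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
from sklearn.metrics import roc_auc_score

from . import nn
from .io import ChannelStack, ProbabilityMap, BinaryMask
from .patches import PatchSet, split_train_val

__all__ = [
    "ModelConfig",
    "TrainConfig",
    "VesselUNet",
    "build_model",
    "train",
    "predict_full",
    "threshold",
    "save_model",
    "load_model",
]


@dataclass
class ModelConfig:
    in_channels: int = 4
    depth: int = 4
    base_filters: int = 32
    patch_size: int = 64
    standardize: bool = True  # per-channel z-scoring of the input stack

    def __post_init__(self) -> None:
        if self.in_channels not in (1, 3, 4):
            raise ValueError("in_channels must be 1, 3 or 4 (channel combo)")
        if self.patch_size % (2**self.depth) != 0:
            raise ValueError(
                f"patch_size {self.patch_size} not divisible by 2^depth={2**self.depth}"
            )


@dataclass
class TrainConfig:
    learning_rate: float = 0.01
    batch_size: int = 32
    epochs: int = 10
    seed: int = 0
    momentum: float = 0.0  # plain SGD by default

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


class VesselUNet:
    """Encoder-decoder with residual conv sets and strided downsampling."""

    def __init__(self, cfg: ModelConfig, seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        f = [cfg.base_filters * 2**i for i in range(cfg.depth + 1)]
        self.enc = [nn.ResidualConvSet(cfg.in_channels, f[0], rng)]
        self.down = []
        for i in range(1, cfg.depth + 1):
            self.down.append((nn.Conv2d(f[i - 1], f[i], 3, stride=2, rng=rng), nn.ReLU()))
            self.enc.append(nn.ResidualConvSet(f[i], f[i], rng))
        self.up = []
        self.dec = []
        for i in range(cfg.depth, 0, -1):
            self.up.append(nn.ConvTranspose2d(f[i], f[i - 1], rng))
            self.dec.append(nn.ResidualConvSet(2 * f[i - 1], f[i - 1], rng))
        self.head = nn.Conv2d(f[0], 2, k=1, rng=rng)
        # input standardization buffers (identity until set from data)
        self.in_mean = np.zeros((cfg.in_channels, 1, 1), dtype=np.float32)
        self.in_std = np.ones((cfg.in_channels, 1, 1), dtype=np.float32)
        self._stats_set = False

    def set_input_stats(self, x: np.ndarray) -> None:
        """Freeze per-channel standardization statistics from training data."""
        self.in_mean = x.mean(axis=(0, 2, 3), keepdims=True)[0].astype(np.float32)
        self.in_std = (x.std(axis=(0, 2, 3), keepdims=True)[0] + 1e-6).astype(np.float32)
        self._stats_set = True

    # -- introspection ---------------------------------------------------
    def iter_layers(self):
        yield self.enc[0]
        for (dwn, act), enc in zip(self.down, self.enc[1:]):
            yield dwn
            yield act
            yield enc
        for up, dec in zip(self.up, self.dec):
            yield up
            yield dec
        yield self.head

    def parameters(self):
        out = []
        for layer in self.iter_layers():
            out.extend(layer.parameters())
        return out

    def zero_grad(self) -> None:
        for _, g in self.parameters():
            g[...] = 0.0

    # -- forward/backward ------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.ascontiguousarray(x)
        if x.dtype not in (np.float32, np.float64):
            x = x.astype(np.float32)
        if self.cfg.standardize:
            x = (x - self.in_mean) / self.in_std
        skips = []
        h = self.enc[0].forward(x)
        for (dwn, act), enc in zip(self.down, self.enc[1:]):
            skips.append(h)
            h = enc.forward(act.forward(dwn.forward(h)))
        self._skip_channels = []
        for up, dec, skip in zip(self.up, self.dec, reversed(skips)):
            u = up.forward(h)
            h = dec.forward(np.concatenate([skip, u], axis=1))
            self._skip_channels.append(skip.shape[1])
        return self.head.forward(h)

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.head.backward(dlogits)
        dskips = []
        for up, dec, cskip in zip(
            reversed(self.up), reversed(self.dec), reversed(self._skip_channels)
        ):
            dcat = dec.backward(d)
            dskips.append(dcat[:, :cskip])
            d = up.backward(dcat[:, cskip:])
        # dskips were collected from the shallowest decoder stage first
        for (dwn, act), enc, dskip in zip(
            reversed(self.down), reversed(self.enc[1:]), reversed(dskips)
        ):
            d = dwn.backward(act.backward(enc.backward(d)))
            d = d + dskip
        self.enc[0].backward(d)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Vessel-class softmax probability, (N, H, W)."""
        return nn.softmax(self.forward(x), axis=1)[:, 1]


def build_model(cfg: ModelConfig, seed: int = 0) -> VesselUNet:
    return VesselUNet(cfg, seed=seed)


@dataclass
class EpochLog:
    epoch: int
    train_loss: float
    val_auc: float | None


def train(
    net: VesselUNet,
    patch_source: Callable[[int], PatchSet] | PatchSet,
    tcfg: TrainConfig,
    train_fraction: float = 0.9,
    resample_validation: bool = True,
) -> list[EpochLog]:
    """SGD training loop with per-epoch patch resampling.

    ``patch_source`` is either a fixed :class:`PatchSet` or a callable
    mapping an epoch index to a freshly sampled set (pass
    ``lambda e: sample_patches(..., seed=seed + e)`` for the per-epoch
    resampling protocol).  Each epoch's set is split positionally 90/10
    into train/validation; validation AUC is logged per epoch.
    """
    logs: list[EpochLog] = []
    velocity = None
    fixed_val = None
    for epoch in range(tcfg.epochs):
        ps = patch_source(epoch) if callable(patch_source) else patch_source
        tr, va = split_train_val(ps, train_fraction)
        if net.cfg.standardize and not net._stats_set:
            net.set_input_stats(tr.x)
        if not resample_validation:
            if fixed_val is None:
                fixed_val = va
            va = fixed_val
        if tr.x.shape[1] != net.cfg.in_channels:
            raise ValueError(
                f"patch channel count {tr.x.shape[1]} does not match the "
                f"model ({net.cfg.in_channels})"
            )
        losses = []
        n = len(tr)
        for start in range(0, n, tcfg.batch_size):
            xb = tr.x[start : start + tcfg.batch_size].astype(np.float32)
            yb = tr.y[start : start + tcfg.batch_size]
            net.zero_grad()
            logits = net.forward(xb)
            loss, dlogits = nn.softmax_cce(logits, yb)
            net.backward(dlogits.astype(np.float32))
            params = net.parameters()
            if tcfg.momentum > 0:
                if velocity is None:
                    velocity = [np.zeros_like(p) for p, _ in params]
                for v, (p, g) in zip(velocity, params):
                    v *= tcfg.momentum
                    v -= tcfg.learning_rate * g
                    p += v
            else:
                for p, g in params:
                    p -= tcfg.learning_rate * g
            losses.append(loss)
        val_auc = None
        if len(va):
            probs = []
            for start in range(0, len(va), tcfg.batch_size):
                probs.append(net.predict_proba(va.x[start : start + tcfg.batch_size].astype(np.float32)))
            p = np.concatenate(probs).ravel()
            y = va.y.ravel()
            if y.any() and not y.all():
                val_auc = float(roc_auc_score(y.astype(int), p))
        logs.append(EpochLog(epoch, float(np.mean(losses)), val_auc))
    return logs


def predict_full(
    net: VesselUNet,
    stack: ChannelStack,
    tile: int = 64,
    overlap: int = 0,
) -> ProbabilityMap:
    """Tile a full image, predict per tile, and average the overlaps."""
    if stack.n_channels != net.cfg.in_channels:
        raise ValueError(
            f"stack has {stack.n_channels} channels, model expects "
            f"{net.cfg.in_channels}"
        )
    if not (0 <= overlap < tile):
        raise ValueError("overlap must lie in [0, tile)")
    h, w = stack.shape
    step = tile - overlap
    ph = int(np.ceil(max(h - overlap, 1) / step)) * step + overlap
    pw = int(np.ceil(max(w - overlap, 1) / step)) * step + overlap
    x = np.zeros((stack.n_channels, ph, pw), dtype=np.float32)
    x[:, :h, :w] = stack.channels
    acc = np.zeros((ph, pw), dtype=np.float64)
    cnt = np.zeros((ph, pw), dtype=np.float64)
    tiles, coords = [], []
    for r in range(0, ph - tile + 1, step):
        for c in range(0, pw - tile + 1, step):
            tiles.append(x[:, r : r + tile, c : c + tile])
            coords.append((r, c))
    batch = 32
    probs = []
    for start in range(0, len(tiles), batch):
        probs.append(net.predict_proba(np.stack(tiles[start : start + batch])))
    probs = np.concatenate(probs)
    for (r, c), p in zip(coords, probs):
        acc[r : r + tile, c : c + tile] += p
        cnt[r : r + tile, c : c + tile] += 1.0
    out = acc / cnt
    return ProbabilityMap(out[:h, :w])


def threshold(prob: ProbabilityMap | np.ndarray, t_h: float) -> BinaryMask:
    """Binary segmentation: pixel is vessel iff probability >= t_h."""
    if not (0.0 <= t_h <= 1.0):
        raise ValueError("threshold must lie in [0, 1]")
    arr = prob.pixels if isinstance(prob, ProbabilityMap) else np.asarray(prob)
    return BinaryMask(arr >= t_h, role="segmentation")


def save_model(net: VesselUNet, path: str | Path) -> None:
    """Checkpoint: flat parameter arrays plus the embedded config."""
    arrays = {f"p{i}": p for i, (p, _) in enumerate(net.parameters())}
    arrays["in_mean"] = net.in_mean
    arrays["in_std"] = net.in_std
    arrays["config"] = np.frombuffer(
        json.dumps(net.cfg.__dict__).encode(), dtype=np.uint8
    )
    np.savez(Path(path), **arrays)


def load_model(path: str | Path) -> VesselUNet:
    data = np.load(Path(path))
    cfg = ModelConfig(**json.loads(bytes(data["config"]).decode()))
    net = VesselUNet(cfg, seed=0)
    for i, (p, _) in enumerate(net.parameters()):
        p[...] = data[f"p{i}"]
    net.in_mean = data["in_mean"]
    net.in_std = data["in_std"]
    net._stats_set = True
    return net
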