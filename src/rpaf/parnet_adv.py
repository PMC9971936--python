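"""ParNet-adv: a shallow three-stream parallel CNN for RP-image classification.

The network keeps the non-deep ParNet layout — three parallel streams at
decreasing resolution built from RepVGG-SSE-style blocks (1x1 branch +
spatial-filter branch + squeeze-excitation skip gate, summed and passed
through SiLU), joined by fusion blocks and finished with global average
pooling and a fully connected head.  The "-adv" variant replaces the 3x3
spatial filter with a factorized 1x7 -> 7x1 pair, widening the receptive
field at similar cost; ``kernel_mode="square_3x3"`` rebuilds plain ParNet
for ablations.

Depth convention: parameterized stages on the longest input->output path.
The factorized 1x7/7x1 pair counts as ONE spatial-filter stage (it replaces
one 3x3), so depth is 12 for both kernel modes:
2 downsampling + 6 stream blocks + 2 fusion + 1 final downsampling + 1 FC.
All three stream paths count 12 under this layout (streams 2 and 3 trade
stream blocks for extra downsampling stages).

Block internals beyond the published stream/fusion sketch are a
reconstruction following the original ParNet design.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from rpaf.nn import (
    Adam,
    AvgPoolCeil2,
    BatchNorm2d,
    Conv2d,
    GlobalAvgPool,
    Layer,
    Linear,
    SiLU,
    SqueezeExcite,
    softmax_cross_entropy,
    softmax_probs,
)

KERNEL_MODES = ("asymmetric_1x7_7x1", "square_3x3")

# blocks per stream; together with the downsampling/fusion stages every
# stream path counts 12 parameterized stages
_STREAM_BLOCKS = (6, 5, 5)


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and training hyperparameters.

    depth and n_streams are architecture constants (12 and 3); stream
    widths, input size and channel count scale the model between the
    299x299 native profile and small CPU profiles.
    """

    kernel_mode: str = "asymmetric_1x7_7x1"
    stream_widths: tuple[int, int, int] = (16, 32, 64)
    input_size: int = 64
    in_channels: int = 3
    n_classes: int = 2
    activation: str = "silu"
    lr: float = 1e-3
    batch_size: int = 64
    epochs: int = 10
    weight_decay: float = 0.0
    loss: str = "cross_entropy"
    seed: int = 0
    factorization_order: tuple[str, str] = ("1x7", "7x1")

    depth: int = field(default=12, init=False)
    n_streams: int = field(default=3, init=False)

    def validate(self) -> None:
        if self.kernel_mode not in KERNEL_MODES:
            raise ValueError(f"kernel_mode must be one of {KERNEL_MODES}")
        if len(self.stream_widths) != 3 or min(self.stream_widths) < 1:
            raise ValueError("stream_widths must be three positive channel counts")
        if self.input_size < 32:
            raise ValueError("input_size must be >= 32 for the downsampling schedule")
        if self.in_channels < 1 or self.n_classes < 2:
            raise ValueError("invalid channel or class count")
        if self.lr <= 0 or self.batch_size < 1 or self.epochs < 1:
            raise ValueError("invalid training hyperparameters")
        if set(self.factorization_order) != {"1x7", "7x1"}:
            raise ValueError("factorization_order must contain '1x7' and '7x1'")


def native_config(n_leads: int = 1, **overrides) -> ModelConfig:
    """Native-scale profile: 299x299 inputs, batch 64, lr 0.001."""
    return replace(
        ModelConfig(stream_widths=(64, 128, 256), input_size=299, in_channels=3 * n_leads),
        **overrides,
    )


def desk_config(n_leads: int = 1, **overrides) -> ModelConfig:
    """CPU-friendly profile: 64x64 inputs, widths 16/32/64."""
    return replace(
        ModelConfig(stream_widths=(16, 32, 64), input_size=64, in_channels=3 * n_leads, batch_size=16),
        **overrides,
    )


def mini_config(n_leads: int = 1, **overrides) -> ModelConfig:
    """Smallest test profile: 32x32 inputs, widths 8/16/32."""
    return replace(
        ModelConfig(stream_widths=(8, 16, 32), input_size=32, in_channels=3 * n_leads, batch_size=8, epochs=8),
        **overrides,
    )


class _Down(Layer):
    """Downsampling block: stride-2 3x3 conv branch + pooled 1x1 projection branch."""

    def __init__(self, cin, cout, rng):
        self.conv = Conv2d(cin, cout, 3, stride=2, pad=1, rng=rng)
        self.bn_conv = BatchNorm2d(cout)
        self.pool = AvgPoolCeil2()
        self.proj = Conv2d(cin, cout, 1, rng=rng)
        self.bn_proj = BatchNorm2d(cout)
        self.act = SiLU()

    def forward(self, x):
        a = self.bn_conv(self.conv(x))
        b = self.bn_proj(self.proj(self.pool(x)))
        return self.act(a + b)

    def backward(self, dout):
        d = self.act.backward(dout)
        dx = self.conv.backward(self.bn_conv.backward(d))
        dx += self.pool.backward(self.proj.backward(self.bn_proj.backward(d)))
        return dx


class _Block(Layer):
    """Stream block: 1x1 branch + spatial-filter branch + SE skip gate -> SiLU.

    kernel_mode picks the spatial filter: a single 3x3 (plain ParNet) or the
    factorized 1x7 -> 7x1 pair (ParNet-adv), counted as one stage either way.
    """

    def __init__(self, channels, kernel_mode, rng, order=("1x7", "7x1")):
        self.pw = Conv2d(channels, channels, 1, rng=rng)
        self.bn_pw = BatchNorm2d(channels)
        self.kernel_mode = kernel_mode
        if kernel_mode == "square_3x3":
            self.spatial = [Conv2d(channels, channels, 3, pad=1, rng=rng)]
        else:
            shapes = {"1x7": ((1, 7), (0, 3)), "7x1": ((7, 1), (3, 0))}
            self.spatial = [Conv2d(channels, channels, shapes[o][0], pad=shapes[o][1], rng=rng) for o in order]
        self.bn_spatial = BatchNorm2d(channels)
        self.sse = SqueezeExcite(channels, rng=rng)
        self.act = SiLU()

    def _spatial_forward(self, x):
        for conv in self.spatial:
            x = conv(x)
        return x

    def _spatial_backward(self, d):
        for conv in reversed(self.spatial):
            d = conv.backward(d)
        return d

    def forward(self, x):
        a = self.bn_pw(self.pw(x))
        b = self.bn_spatial(self._spatial_forward(x))
        c = self.sse(x)
        return self.act(a + b + c)

    def backward(self, dout):
        d = self.act.backward(dout)
        dx = self.pw.backward(self.bn_pw.backward(d))
        dx += self._spatial_backward(self.bn_spatial.backward(d))
        dx += self.sse.backward(d)
        return dx


class _Fusion(Layer):
    """Fuse a higher-resolution stream into a lower one.

    The high-res input is ceil-pooled to the partner's resolution, the two
    are concatenated along channels and mixed by a 1x1 conv + BN + SiLU.
    """

    def __init__(self, c_high, c_low, cout, rng):
        self.pool = AvgPoolCeil2()
        self.mix = Conv2d(c_high + c_low, cout, 1, rng=rng)
        self.bn = BatchNorm2d(cout)
        self.act = SiLU()
        self.c_high = c_high

    def forward(self, high, low):
        hp = self.pool(high)
        if hp.shape[2:] != low.shape[2:]:
            raise ValueError(f"fusion resolution mismatch: {hp.shape} vs {low.shape}")
        z = np.concatenate([hp, low], axis=1)
        return self.act(self.bn(self.mix(z)))

    def backward(self, dout):
        d = self.mix.backward(self.bn.backward(self.act.backward(dout)))
        d_high = self.pool.backward(d[:, : self.c_high])
        d_low = d[:, self.c_high :]
        return d_high, d_low


class ParNetAdvNet(Layer):
    """The full three-stream network graph."""

    def __init__(self, cfg: ModelConfig):
        cfg.validate()
        rng = np.random.default_rng(cfg.seed)
        w1, w2, w3 = cfg.stream_widths
        b1, b2, b3 = _STREAM_BLOCKS
        self.cfg = cfg
        self.d1 = _Down(cfg.in_channels, w1, rng)
        self.d2 = _Down(w1, w1, rng)
        self.d3 = _Down(w1, w2, rng)
        self.d4 = _Down(w2, w3, rng)
        order = cfg.factorization_order
        self.stream1 = [_Block(w1, cfg.kernel_mode, rng, order) for _ in range(b1)]
        self.stream2 = [_Block(w2, cfg.kernel_mode, rng, order) for _ in range(b2)]
        self.stream3 = [_Block(w3, cfg.kernel_mode, rng, order) for _ in range(b3)]
        self.fuse12 = _Fusion(w1, w2, w2, rng)
        self.fuse23 = _Fusion(w2, w3, w3, rng)
        self.final_down = _Down(w3, w3, rng)
        self.gap = GlobalAvgPool()
        self.fc = Linear(w3, cfg.n_classes, rng=rng)

    # -- forward/backward ------------------------------------------------
    def forward(self, x):
        h1 = self.d1(x)
        h2 = self.d2(h1)
        a = h2
        for blk in self.stream1:
            a = blk(a)
        h3 = self.d3(h2)
        b = h3
        for blk in self.stream2:
            b = blk(b)
        h4 = self.d4(h3)
        c = h4
        for blk in self.stream3:
            c = blk(c)
        u = self.fuse12.forward(a, b)
        v = self.fuse23.forward(u, c)
        z = self.final_down(v)
        return self.fc(self.gap(z))

    def backward(self, dlogits):
        dz = self.gap.backward(self.fc.backward(dlogits))
        dv = self.final_down.backward(dz)
        du, dc = self.fuse23.backward(dv)
        da, db = self.fuse12.backward(du)
        for blk in reversed(self.stream3):
            dc = blk.backward(dc)
        dh3 = self.d4.backward(dc)
        for blk in reversed(self.stream2):
            db = blk.backward(db)
        dh3 += db
        dh2 = self.d3.backward(dh3)
        for blk in reversed(self.stream1):
            da = blk.backward(da)
        dh2 += da
        dh1 = self.d2.backward(dh2)
        return self.d1.backward(dh1)

    # -- introspection ---------------------------------------------------
    def longest_path_depth(self) -> int:
        """Parameterized stages on the longest input->output path."""
        tail = 2 + 1 + 1  # fuse12+fuse23, final downsampling, FC head
        paths = (
            2 + len(self.stream1) + tail,            # d1,d2 -> stream 1
            3 + len(self.stream2) + tail,            # d1..d3 -> stream 2
            4 + len(self.stream3) + (tail - 1),      # d1..d4 -> stream 3 (skips fuse12)
        )
        return max(paths)


@dataclass
class TrainedModel:
    """A (possibly untrained) network plus its config and training history."""

    net: ParNetAdvNet
    config: ModelConfig
    history: list[dict] = field(default_factory=list)

    # sklearn-style adapters so evaluation/crossval and lead selection can
    # treat this like any estimator
    def fit(self, X: np.ndarray, y: np.ndarray) -> "TrainedModel":
        return train(self, X, y)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return predict(self, X)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)

    # -- persistence -----------------------------------------------------
    def save(self, path: str | Path) -> Path:
        """Write weights (npz) and a JSON sidecar of the config and history."""
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        params = self.net.params()
        arrays = {f"p{i}": p.data for i, p in enumerate(params)}
        bns = [l for l in _walk(self.net) if isinstance(l, BatchNorm2d)]
        for i, bn in enumerate(bns):
            arrays[f"rm{i}"] = bn.running_mean
            arrays[f"rv{i}"] = bn.running_var
        np.savez(path, **arrays)
        sidecar = path.with_suffix(".json")
        cfg = asdict(self.config)
        sidecar.write_text(json.dumps({"config": cfg, "history": self.history}, indent=1))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        cfg_dict = {k: v for k, v in sidecar["config"].items() if k not in ("depth", "n_streams")}
        for key in ("stream_widths", "factorization_order"):
            cfg_dict[key] = tuple(cfg_dict[key])
        cfg = ModelConfig(**cfg_dict)
        model = build_model(cfg)
        data = np.load(path)
        for i, p in enumerate(model.net.params()):
            p.data[...] = data[f"p{i}"]
        bns = [l for l in _walk(model.net) if isinstance(l, BatchNorm2d)]
        for i, bn in enumerate(bns):
            bn.running_mean[...] = data[f"rm{i}"]
            bn.running_var[...] = data[f"rv{i}"]
        model.history = sidecar["history"]
        return model


def _walk(layer: Layer):
    yield layer
    for v in layer.__dict__.values():
        if isinstance(v, Layer):
            yield from _walk(v)
        elif isinstance(v, (list, tuple)):
            for u in v:
                if isinstance(u, Layer):
                    yield from _walk(u)


def build_model(cfg: ModelConfig) -> TrainedModel:
    """Construct an untrained ParNet-adv (or plain ParNet) per the config."""
    return TrainedModel(net=ParNetAdvNet(cfg), config=cfg)


def _check_images(X: np.ndarray, cfg: ModelConfig) -> np.ndarray:
    X = np.asarray(X, dtype=np.float32)
    if X.ndim != 4:
        raise ValueError("images must be (batch, channels, height, width)")
    if X.shape[1] != cfg.in_channels:
        raise ValueError(f"expected {cfg.in_channels} channels, got {X.shape[1]}")
    if X.shape[2] != X.shape[3]:
        raise ValueError("images must be square")
    return X


def train(model: TrainedModel, images: np.ndarray, labels: np.ndarray, cfg: Optional[ModelConfig] = None) -> TrainedModel:
    """Train with cross-entropy and Adam; deterministic per config seed.

    Per-epoch mean loss and training accuracy are appended to
    ``model.history``.
    """
    cfg = cfg if cfg is not None else model.config
    X = _check_images(images, cfg)
    y = np.asarray(labels, dtype=int)
    if len(X) == 0:
        raise ValueError("empty training set")
    if len(X) != len(y):
        raise ValueError("images and labels differ in length")
    rng = np.random.default_rng(cfg.seed + 1)
    opt = Adam(model.net.params(), lr=cfg.lr, weight_decay=cfg.weight_decay)
    n = len(X)
    for epoch in range(cfg.epochs):
        model.net.set_training(True)
        order = rng.permutation(n)
        losses, correct = [], 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            logits = model.net.forward(X[idx])
            loss, dlogits = softmax_cross_entropy(logits, y[idx])
            opt.zero_grad()
            model.net.backward(dlogits)
            opt.step()
            losses.append(loss)
            correct += int((logits.argmax(axis=1) == y[idx]).sum())
        model.history.append(
            {"epoch": epoch, "loss": float(np.mean(losses)), "train_acc": correct / n}
        )
    model.net.set_training(False)
    return model


def predict(model: TrainedModel, images: np.ndarray) -> np.ndarray:
    """Class probabilities (rows sum to 1), batch-partition invariant.

    Inference always runs with batch-norm in inference mode (running
    statistics), so the output for a sample does not depend on its batch.
    """
    cfg = model.config
    X = _check_images(images, cfg)
    model.net.set_training(False)
    out = []
    step = max(1, cfg.batch_size)
    for start in range(0, len(X), step):
        logits = model.net.forward(X[start : start + step])
        out.append(softmax_probs(logits.astype(np.float64)))
    return np.concatenate(out, axis=0)


def stack_leads(images_per_lead: Sequence) -> np.ndarray:
    """Concatenate per-lead RGB images along the channel axis -> (3*k, H, W).

    Accepts RpImage objects or (H, W, 3)/(3, H, W) arrays; all must share
    one size.
    """
    chans = []
    size = None
    for img in images_per_lead:
        arr = img.to_chw() if hasattr(img, "to_chw") else np.asarray(img)
        if arr.ndim != 3:
            raise ValueError("each lead image must be a 3-channel raster")
        if arr.shape[-1] == 3 and arr.shape[0] != 3:
            arr = arr.transpose(2, 0, 1)
        if size is None:
            size = arr.shape[1:]
        elif arr.shape[1:] != size:
            raise ValueError(f"lead image size mismatch: {arr.shape[1:]} vs {size}")
        chans.append(arr)
    if not chans:
        raise ValueError("no lead images given")
    return np.concatenate(chans, axis=0)
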