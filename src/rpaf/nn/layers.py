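"""Layer primitives with explicit forward/backward passes (NCHW layout).

Each layer caches what its backward pass needs during forward; backward
returns the gradient with respect to the input and accumulates parameter
gradients in place.  Convolutions use im2col + matmul; weights follow He
initialization from a caller-supplied Generator so the whole network is
seed-reproducible.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit


class Param:
    """A learnable array with an accumulated gradient."""

    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = data
        self.grad = np.zeros_like(data)


class Layer:
    """Base class; parameter/mode traversal walks attributes recursively."""

    training: bool = True

    def params(self) -> list[Param]:
        out: list[Param] = []
        for v in self.__dict__.values():
            if isinstance(v, Param):
                out.append(v)
            elif isinstance(v, Layer):
                out.extend(v.params())
            elif isinstance(v, (list, tuple)):
                for u in v:
                    if isinstance(u, Layer):
                        out.extend(u.params())
        return out

    def set_training(self, flag: bool) -> None:
        self.training = flag
        for v in self.__dict__.values():
            if isinstance(v, Layer):
                v.set_training(flag)
            elif isinstance(v, (list, tuple)):
                for u in v:
                    if isinstance(u, Layer):
                        u.set_training(flag)

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)

    def n_params(self) -> int:
        return int(sum(p.data.size for p in self.params()))


def _pair(v) -> tuple[int, int]:
    return (v, v) if np.isscalar(v) else tuple(v)


class Conv2d(Layer):
    """2D convolution (cross-correlation) via im2col.

    Bias is off by default because every convolution in the network is
    followed by batch normalization.
    """

    def __init__(self, cin, cout, ksize, stride=1, pad=None, bias=False, rng=None, dtype=np.float32):
        kh, kw = _pair(ksize)
        sh, sw = _pair(stride)
        if pad is None:
            pad = (kh // 2, kw // 2)
        ph, pw = _pair(pad)
        self.cin, self.cout = cin, cout
        self.kh, self.kw, self.sh, self.sw, self.ph, self.pw = kh, kw, sh, sw, ph, pw
        rng = rng if rng is not None else np.random.default_rng(0)
        fan_in = cin * kh * kw
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(cout, fan_in))
        self.W = Param(w.astype(dtype))
        self.b = Param(np.zeros(cout, dtype=dtype)) if bias else None
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        N, C, H, W = x.shape
        if C != self.cin:
            raise ValueError(f"expected {self.cin} input channels, got {C}")
        kh, kw, sh, sw, ph, pw = self.kh, self.kw, self.sh, self.sw, self.ph, self.pw
        if H + 2 * ph < kh or W + 2 * pw < kw:
            raise ValueError("input spatially smaller than kernel")
        if kh == kw == 1 and sh == sw == 1 and ph == pw == 0:
            # pointwise fast path: plain channel matmul
            cols = np.ascontiguousarray(x.transpose(0, 2, 3, 1)).reshape(N * H * W, C)
            Ho, Wo = H, W
        else:
            xp = x if ph == 0 and pw == 0 else np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
            win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
            win = win[:, :, ::sh, ::sw]
            Ho, Wo = win.shape[2], win.shape[3]
            cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(N * Ho * Wo, C * kh * kw)
        out = cols @ self.W.data.T
        if self.b is not None:
            out = out + self.b.data
        self._cache = (cols, x.shape, (Ho, Wo))
        return out.reshape(N, Ho, Wo, self.cout).transpose(0, 3, 1, 2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, xshape, (Ho, Wo) = self._cache
        N, C, H, W = xshape
        kh, kw, sh, sw, ph, pw = self.kh, self.kw, self.sh, self.sw, self.ph, self.pw
        drows = np.ascontiguousarray(dout.transpose(0, 2, 3, 1)).reshape(-1, self.cout)
        self.W.grad += drows.T @ cols
        if self.b is not None:
            self.b.grad += drows.sum(axis=0)
        dcols_rows = drows @ self.W.data
        if kh == kw == 1 and sh == sw == 1 and ph == pw == 0:
            return dcols_rows.reshape(N, H, W, C).transpose(0, 3, 1, 2)
        dcols = dcols_rows.reshape(N, Ho, Wo, C, kh, kw).transpose(0, 3, 1, 2, 4, 5)
        dxp = np.zeros((N, C, H + 2 * ph, W + 2 * pw), dtype=dout.dtype)
        for i in range(kh):
            for j in range(kw):
                dxp[:, :, i : i + sh * Ho : sh, j : j + sw * Wo : sw] += dcols[:, :, :, :, i, j]
        return dxp[:, :, ph : ph + H, pw : pw + W] if (ph or pw) else dxp


class BatchNorm2d(Layer):
    """Batch normalization over (N, H, W) per channel with running statistics."""

    def __init__(self, channels, momentum=0.1, eps=1e-5, dtype=np.float32):
        self.gamma = Param(np.ones(channels, dtype=dtype))
        self.beta = Param(np.zeros(channels, dtype=dtype))
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        ivar = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * ivar[None, :, None, None]
        self._cache = (xhat, ivar)
        return self.gamma.data[None, :, None, None] * xhat + self.beta.data[None, :, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, ivar = self._cache
        axes = (0, 2, 3)
        self.gamma.grad += (dout * xhat).sum(axis=axes)
        self.beta.grad += dout.sum(axis=axes)
        dxhat = dout * self.gamma.data[None, :, None, None]
        if not self.training:
            return dxhat * ivar[None, :, None, None]
        N, C, H, W = dout.shape
        m = N * H * W
        s1 = dxhat.sum(axis=axes, keepdims=True)
        s2 = (dxhat * xhat).sum(axis=axes, keepdims=True)
        return (ivar[None, :, None, None] / m) * (m * dxhat - s1 - xhat * s2)


class SiLU(Layer):
    """Sigmoid-weighted linear unit: x * sigmoid(x)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        s = expit(x)
        self._cache = (x, s)
        return x * s

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x, s = self._cache
        return dout * (s * (1.0 + x * (1.0 - s)))


class Linear(Layer):
    def __init__(self, cin, cout, rng=None, dtype=np.float32):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.W = Param(rng.normal(0.0, np.sqrt(2.0 / cin), size=(cout, cin)).astype(dtype))
        self.b = Param(np.zeros(cout, dtype=dtype))
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._cache = x
        return x @ self.W.data.T + self.b.data

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x = self._cache
        self.W.grad += dout.T @ x
        self.b.grad += dout.sum(axis=0)
        return dout @ self.W.data


class GlobalAvgPool(Layer):
    """(N, C, H, W) -> (N, C) spatial mean."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        N, C, H, W = self._shape
        return np.broadcast_to(dout[:, :, None, None], self._shape) / (H * W)


class AvgPoolCeil2(Layer):
    """2x2 average pooling with stride 2 and ceil-mode output size.

    Border cells average only the samples that exist, so odd input sizes
    halve to ceil(H/2) x ceil(W/2) and the pooled value stays an unbiased
    local mean.
    """

    def forward(self, x: np.ndarray) -> np.ndarray:
        N, C, H, W = x.shape
        Ho, Wo = -(-H // 2), -(-W // 2)
        xp = np.pad(x, ((0, 0), (0, 0), (0, 2 * Ho - H), (0, 2 * Wo - W)))
        s = xp[:, :, 0::2, 0::2] + xp[:, :, 1::2, 0::2] + xp[:, :, 0::2, 1::2] + xp[:, :, 1::2, 1::2]
        rc = np.full(Ho, 2.0)
        cc = np.full(Wo, 2.0)
        if 2 * Ho > H:
            rc[-1] = 1.0
        if 2 * Wo > W:
            cc[-1] = 1.0
        counts = rc[:, None] * cc[None, :]
        self._cache = ((N, C, H, W), counts)
        return (s / counts).astype(x.dtype)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        (N, C, H, W), counts = self._cache
        Ho, Wo = dout.shape[2], dout.shape[3]
        g = dout / counts
        dxp = np.zeros((N, C, 2 * Ho, 2 * Wo), dtype=dout.dtype)
        dxp[:, :, 0::2, 0::2] = g
        dxp[:, :, 1::2, 0::2] = g
        dxp[:, :, 0::2, 1::2] = g
        dxp[:, :, 1::2, 1::2] = g
        return dxp[:, :, :H, :W]


class SqueezeExcite(Layer):
    """Channel gate: y = x * sigmoid(W gap(x) + b), one weight per channel pair.

    The skip-gate branch of the parallel block: global context modulates the
    identity path, adding non-linearity at negligible spatial cost.
    """

    def __init__(self, channels, rng=None, dtype=np.float32):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.W = Param(rng.normal(0.0, np.sqrt(1.0 / channels), size=(channels, channels)).astype(dtype))
        self.b = Param(np.zeros(channels, dtype=dtype))
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        g = x.mean(axis=(2, 3))  # (N, C)
        z = g @ self.W.data.T + self.b.data
        a = expit(z)
        self._cache = (x, g, a)
        return x * a[:, :, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x, g, a = self._cache
        N, C, H, W = x.shape
        dx = dout * a[:, :, None, None]
        da = (dout * x).sum(axis=(2, 3))
        dz = da * a * (1.0 - a)
        self.W.grad += dz.T @ g
        self.b.grad += dz.sum(axis=0)
        dg = dz @ self.W.data
        dx += dg[:, :, None, None] / (H * W)
        return dx


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout
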