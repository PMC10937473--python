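"""Minimal CPU neural-network kernel: conv layers, a U-Net, Adam and TAdam.

Everything is float32 numpy with channels-last layout (N, H, W, C) and
hand-written backpropagation.  The networks used for heatmap regression here
are small (tens of thousands of parameters), for which vectorised numpy
convolutions are entirely adequate and fully deterministic on CPU.

TAdam is Adam with a Student-t based first-moment estimate: the running mean
of the gradient is updated through a robust weight that discounts gradient
samples lying far outside the current second-moment scale, making the
optimizer resilient to heavy-tailed gradient noise.  It follows the published
update rule with degrees of freedom equal to the parameter dimension.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

__all__ = ["Conv2D", "ReLU", "MaxPool2", "Upsample2", "DoubleConv", "UNet",
           "Adam", "TAdam", "make_optimizer"]


class Conv2D:
    """k x k convolution, stride 1, same (zero) padding, channels-last."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator,
                 init: str = "he"):
        self.k = k
        if init == "he":
            std = np.sqrt(2.0 / (k * k * c_in))
            self.W = rng.normal(0.0, std, size=(k, k, c_in, c_out)).astype(np.float32)
        elif init == "zero":
            self.W = np.zeros((k, k, c_in, c_out), dtype=np.float32)
        else:
            raise ValueError(f"unknown init {init!r}")
        self.b = np.zeros(c_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._xpad: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        k, p = self.k, self.k // 2
        n, h, w, _ = x.shape
        xpad = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0))) if p else x
        self._xpad = xpad
        y = np.broadcast_to(self.b, (n, h, w, self.b.shape[0])).copy()
        for di in range(k):
            for dj in range(k):
                y += self._xpad[:, di:di + h, dj:dj + w, :] @ self.W[di, dj]
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        k, p = self.k, self.k // 2
        n, h, w, _ = dy.shape
        self.db[:] = dy.sum(axis=(0, 1, 2))
        dxpad = np.zeros_like(self._xpad)
        for di in range(k):
            for dj in range(k):
                xs = self._xpad[:, di:di + h, dj:dj + w, :]
                self.dW[di, dj] = np.tensordot(xs, dy, axes=([0, 1, 2], [0, 1, 2]))
                dxpad[:, di:di + h, dj:dj + w, :] += dy @ self.W[di, dj].T
        self._xpad = None
        return dxpad[:, p:p + h, p:p + w, :] if p else dxpad

    def tensors(self) -> Iterator[tuple[np.ndarray, np.ndarray]]:
        yield self.W, self.dW
        yield self.b, self.db


class ReLU:
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, 0.0)


class MaxPool2:
    """2x2 max pooling; first maximum wins on ties (deterministic)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        self._in_shape = x.shape
        xr = (x.reshape(n, h // 2, 2, w // 2, 2, c)
              .transpose(0, 1, 3, 5, 2, 4)
              .reshape(n, h // 2, w // 2, c, 4))
        self._idx = np.argmax(xr, axis=-1)
        return np.take_along_axis(xr, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h, w, c = self._in_shape
        dxr = np.zeros((n, h // 2, w // 2, c, 4), dtype=dy.dtype)
        np.put_along_axis(dxr, self._idx[..., None], dy[..., None], axis=-1)
        return (dxr.reshape(n, h // 2, w // 2, c, 2, 2)
                .transpose(0, 1, 4, 2, 5, 3)
                .reshape(n, h, w, c))


class Upsample2:
    """Nearest-neighbour x2 upsampling."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x.repeat(2, axis=1).repeat(2, axis=2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h, w, c = dy.shape
        return dy.reshape(n, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4))


class DoubleConv:
    """(conv3x3 -> ReLU) x 2."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        self.c1 = Conv2D(c_in, c_out, 3, rng)
        self.r1 = ReLU()
        self.c2 = Conv2D(c_out, c_out, 3, rng)
        self.r2 = ReLU()

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self.r2.forward(self.c2.forward(self.r1.forward(self.c1.forward(x))))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return self.c1.backward(self.r1.backward(self.c2.backward(self.r2.backward(dy))))

    def tensors(self):
        yield from self.c1.tensors()
        yield from self.c2.tensors()


class UNet:
    """Encoder-decoder with skip connections and a linear 1x1 head.

    ``depth`` down/upsampling levels, ``base_channels`` at the top level,
    doubling per level.  The head is zero-initialised, so an untrained network
    outputs exactly zero everywhere (decoded as below-confidence).
    """

    def __init__(self, depth: int, base_channels: int, in_channels: int,
                 out_channels: int, seed: int = 0):
        if depth < 1 or base_channels < 1:
            raise ValueError("depth and base_channels must be >= 1")
        rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 0x4E7]))
        self.depth = depth
        self.encs = []
        c = in_channels
        for i in range(depth):
            self.encs.append(DoubleConv(c, base_channels * 2 ** i, rng))
            c = base_channels * 2 ** i
        self.pools = [MaxPool2() for _ in range(depth)]
        self.bottleneck = DoubleConv(c, base_channels * 2 ** depth, rng)
        self.ups = [Upsample2() for _ in range(depth)]
        self.decs = []
        c = base_channels * 2 ** depth
        for i in reversed(range(depth)):
            skip_c = base_channels * 2 ** i
            self.decs.append(DoubleConv(c + skip_c, skip_c, rng))
            c = skip_c
        self.head = Conv2D(c, out_channels, 1, rng, init="zero")

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.shape[1] % 2 ** self.depth or x.shape[2] % 2 ** self.depth:
            raise ValueError("input size must be divisible by 2^depth")
        skips = []
        h = x.astype(np.float32)
        for enc, pool in zip(self.encs, self.pools):
            h = enc.forward(h)
            skips.append(h)
            h = pool.forward(h)
        h = self.bottleneck.forward(h)
        self._skip_channels = []
        for up, dec, skip in zip(self.ups, self.decs, reversed(skips)):
            h = up.forward(h)
            self._skip_channels.append(skip.shape[-1])
            h = dec.forward(np.concatenate([skip, h], axis=-1))
        return self.head.forward(h)

    def backward(self, dy: np.ndarray) -> None:
        h = self.head.backward(dy)
        d_skips = []
        for dec, up, sc in zip(reversed(self.decs), reversed(self.ups),
                               reversed(self._skip_channels)):
            d = dec.backward(h)
            d_skips.append(d[..., :sc])
            h = up.backward(d[..., sc:])
        h = self.bottleneck.backward(h)
        d_skips = d_skips[::-1]  # d_skips[i] pairs with encoder level depth-1-i
        for i in reversed(range(self.depth)):
            h = self.pools[i].backward(h)
            h = h + d_skips[self.depth - 1 - i]
            h = self.encs[i].backward(h)

    def tensors(self) -> list[tuple[np.ndarray, np.ndarray]]:
        out = []
        for enc in self.encs:
            out.extend(enc.tensors())
        out.extend(self.bottleneck.tensors())
        for dec in self.decs:
            out.extend(dec.tensors())
        out.extend(self.head.tensors())
        return out

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p, _ in self.tensors()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for (p, _), w in zip(self.tensors(), weights):
            p[...] = w


class Adam:
    def __init__(self, params: list[tuple[np.ndarray, np.ndarray]], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for i, (p, g) in enumerate(self.params):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            p -= self.lr * (self.m[i] / bc1) / (np.sqrt(self.v[i] / bc2) + self.eps)


class TAdam(Adam):
    """Adam with a Student-t robust first moment (dof = parameter dimension)."""

    def __init__(self, params, lr, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        super().__init__(params, lr, beta1, beta2, eps)
        self.Wt = [self.b1 / (1.0 - self.b1) for _ in params]

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for i, (p, g) in enumerate(self.params):
            d = g.size
            nu = float(d)
            dev = (g - self.m[i]) ** 2 / (self.v[i] + self.eps)
            wt = (nu + d) / (nu + float(dev.sum()))
            self.m[i] = self.m[i] + (wt / (self.Wt[i] + wt)) * (g - self.m[i])
            self.Wt[i] = (2.0 * self.b1 - 1.0) / self.b1 * (self.Wt[i] + wt)
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            p -= self.lr * (self.m[i] / bc1) / (np.sqrt(self.v[i] / bc2) + self.eps)


def make_optimizer(name: str, params, lr: float) -> Adam:
    name = name.upper()
    if name == "ADAM":
        return Adam(params, lr)
    if name == "TADAM":
        return TAdam(params, lr)
    raise ValueError(f"unknown optimizer {name!r}")
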