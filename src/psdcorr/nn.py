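"""Minimal NumPy neural-network engine for volumetric regression.

Implements exactly the pieces the field-map predictor needs: 3D convolution
(kernel 1 or 3, stride 1 or 2, zero padding) with hand-derived backward
passes, ReLU, nearest-neighbour upsampling, residual blocks, a U-Net with
three ResNet stages per side, an L1 loss and an Adam optimizer.  Forward and
backward convolutions are organised as one matrix product per kernel offset
(27 for k=3), which keeps memory at one padded copy of the activation and
runs through BLAS.

Gradients are verified against central finite differences in the test
suite.  All randomness is drawn from a single seeded generator at
construction time, so identical seeds give bit-identical weights.
"""

from __future__ import annotations

import hashlib
from itertools import product

import numpy as np


class Conv3d:
    """3D convolution, kernel k, stride s, zero padding p (default "same")."""

    def __init__(self, cin: int, cout: int, k: int = 3, stride: int = 1,
                 pad: int | None = None, rng: np.random.Generator | None = None):
        self.cin, self.cout, self.k, self.stride = cin, cout, k, stride
        self.pad = (k - 1) // 2 if pad is None else pad
        rng = rng or np.random.default_rng(0)
        std = np.sqrt(2.0 / (cin * k**3))  # He init for ReLU nets
        self.W = (rng.standard_normal((cout, cin, k, k, k)) * std).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._xp = None

    def _out_shape(self, dhw):
        p, s, k = self.pad, self.stride, self.k
        return tuple((n + 2 * p - k) // s + 1 for n in dhw)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        p, s, k = self.pad, self.stride, self.k
        B = x.shape[0]
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p))) if p else x
        out = self._out_shape(x.shape[2:])
        y = np.broadcast_to(self.b[None, :, None, None, None],
                            (B, self.cout) + out).copy()
        for t0, t1, t2 in product(range(k), repeat=3):
            xs = xp[:, :, t0:t0 + s * out[0]:s, t1:t1 + s * out[1]:s,
                    t2:t2 + s * out[2]:s]
            y += np.einsum("oc,bcxyz->boxyz", self.W[:, :, t0, t1, t2], xs,
                           optimize=True)
        if train:
            self._xp, self._in_shape = xp, x.shape
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        p, s, k = self.pad, self.stride, self.k
        xp = self._xp
        out = dy.shape[2:]
        self.db[:] = dy.sum(axis=(0, 2, 3, 4))
        dxp = np.zeros_like(xp)
        for t0, t1, t2 in product(range(k), repeat=3):
            sl = (slice(None), slice(None),
                  slice(t0, t0 + s * out[0], s),
                  slice(t1, t1 + s * out[1], s),
                  slice(t2, t2 + s * out[2], s))
            self.dW[:, :, t0, t1, t2] = np.einsum("boxyz,bcxyz->oc", dy, xp[sl],
                                                  optimize=True)
            dxp[sl] += np.einsum("oc,boxyz->bcxyz", self.W[:, :, t0, t1, t2], dy,
                                 optimize=True)
        self._xp = None
        if p:
            return dxp[:, :, p:-p, p:-p, p:-p]
        return dxp

    def convs(self):
        return [self]


class ReLU:
    """Leaky rectifier (slope 0.1 on the negative side).

    The leak keeps every unit trainable; with the narrow layers used at
    desk scale, hard rectification can permanently silence a meaningful
    fraction of a layer at initialization.
    """

    slope = 0.1

    def forward(self, x, train=True):
        y = np.where(x > 0, x, self.slope * x)
        if train:
            self._mask = np.where(x > 0, 1.0, self.slope).astype(x.dtype)
        return y

    def backward(self, dy):
        return dy * self._mask


class Upsample2:
    """Nearest-neighbour x2 upsampling; backward sums each 2x2x2 block."""

    def forward(self, x, train=True):
        return x.repeat(2, axis=2).repeat(2, axis=3).repeat(2, axis=4)

    def backward(self, dy):
        B, C, D, H, W = dy.shape
        return dy.reshape(B, C, D // 2, 2, H // 2, 2, W // 2, 2).sum(axis=(3, 5, 7))


class ResBlock:
    """conv-relu-conv plus (projected) identity shortcut, ReLU on the sum."""

    def __init__(self, cin, cout, rng):
        self.conv1 = Conv3d(cin, cout, rng=rng)
        self.relu1 = ReLU()
        self.conv2 = Conv3d(cout, cout, rng=rng)
        self.proj = Conv3d(cin, cout, k=1, pad=0, rng=rng) if cin != cout else None
        self.relu2 = ReLU()

    def forward(self, x, train=True):
        h = self.relu1.forward(self.conv1.forward(x, train), train)
        h = self.conv2.forward(h, train)
        s = self.proj.forward(x, train) if self.proj is not None else x
        return self.relu2.forward(h + s, train)

    def backward(self, dy):
        dz = self.relu2.backward(dy)
        dx = self.conv1.backward(self.relu1.backward(self.conv2.backward(dz)))
        dx = dx + (self.proj.backward(dz) if self.proj is not None else dz)
        return dx

    def convs(self):
        out = self.conv1.convs() + self.conv2.convs()
        if self.proj is not None:
            out += self.proj.convs()
        return out


class UNet3D:
    """U-Net regressor: stride-2 ResNet encoder stages, upsample+concat
    ResNet decoder stages, single-channel in and out, same-shape output.

    Input spatial dimensions must be divisible by 2**levels.
    """

    def __init__(self, levels: int = 3, base_channels: int = 8,
                 in_channels: int = 1, out_channels: int = 1, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.levels = levels
        ch = [base_channels * 2**i for i in range(levels + 1)]
        self.ch = ch
        self.stem = Conv3d(in_channels, ch[0], rng=rng)
        self.stem_relu = ReLU()
        self.down = []
        for i in range(levels):
            self.down.append({
                "conv": Conv3d(ch[i], ch[i + 1], stride=2, rng=rng),
                "relu": ReLU(),
                "res": ResBlock(ch[i + 1], ch[i + 1], rng=rng),
            })
        self.up = []
        for i in reversed(range(levels)):
            self.up.append({
                "upsample": Upsample2(),
                "res": ResBlock(ch[i + 1] + ch[i], ch[i], rng=rng),
                "level": i,
            })
        self.head = Conv3d(ch[0], out_channels, rng=rng)

    def _check(self, x):
        div = 2**self.levels
        if any(n % div for n in x.shape[2:]):
            raise ValueError(
                f"input spatial shape {x.shape[2:]} must be divisible by {div}"
            )

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._check(x)
        x = np.ascontiguousarray(x, dtype=self.stem.W.dtype)
        h = self.stem_relu.forward(self.stem.forward(x, train), train)
        skips = [h]
        for st in self.down:
            h = st["relu"].forward(st["conv"].forward(h, train), train)
            h = st["res"].forward(h, train)
            skips.append(h)
        self._skip_ch = [s.shape[1] for s in skips]
        for st in self.up:
            h = st["upsample"].forward(h, train)
            h = np.concatenate([h, skips[st["level"]]], axis=1)
            h = st["res"].forward(h, train)
        return self.head.forward(h, train)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        d = self.head.backward(dy)
        dskips = [None] * (self.levels + 1)
        for st in reversed(self.up):
            d = st["res"].backward(d)
            c_up = self.ch[st["level"] + 1]
            d_up, d_skip = d[:, :c_up], d[:, c_up:]
            dskips[st["level"]] = d_skip
            d = st["upsample"].backward(np.ascontiguousarray(d_up))
        for i, st in reversed(list(enumerate(self.down))):
            if dskips[i + 1] is not None:
                d = d + dskips[i + 1]
            d = st["res"].backward(d)
            d = st["conv"].backward(st["relu"].backward(d))
        if dskips[0] is not None:
            d = d + dskips[0]
        return self.stem.backward(self.stem_relu.backward(d))

    # -- parameter plumbing -------------------------------------------------
    def convs(self) -> list[Conv3d]:
        out = self.stem.convs()
        for st in self.down:
            out += st["conv"].convs() + st["res"].convs()
        for st in self.up:
            out += st["res"].convs()
        return out + self.head.convs()

    def n_parameters(self) -> int:
        return sum(c.W.size + c.b.size for c in self.convs())

    def get_weights(self) -> list[np.ndarray]:
        out = []
        for c in self.convs():
            out += [c.W.copy(), c.b.copy()]
        return out

    def set_weights(self, weights: list[np.ndarray]) -> None:
        it = iter(weights)
        for c in self.convs():
            c.W = np.asarray(next(it), dtype=c.W.dtype).reshape(c.W.shape).copy()
            c.b = np.asarray(next(it), dtype=c.b.dtype).reshape(c.b.shape).copy()
            c.dW = np.zeros_like(c.W)
            c.db = np.zeros_like(c.b)

    def astype(self, dtype) -> "UNet3D":
        for c in self.convs():
            c.W = c.W.astype(dtype)
            c.b = c.b.astype(dtype)
            c.dW = np.zeros_like(c.W)
            c.db = np.zeros_like(c.b)
        return self

    def weights_hash(self) -> str:
        h = hashlib.sha256()
        for c in self.convs():
            h.update(np.ascontiguousarray(c.W, dtype=np.float32).tobytes())
            h.update(np.ascontiguousarray(c.b, dtype=np.float32).tobytes())
        return h.hexdigest()


def l1_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean absolute error and its (sub)gradient w.r.t. the prediction."""
    diff = pred - target
    loss = float(np.mean(np.abs(diff)))
    grad = np.sign(diff).astype(pred.dtype) / diff.size
    return loss, grad


class Adam:
    """Adam over the convolution parameters of a network."""

    def __init__(self, model: UNet3D, lr: float = 2e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        if not all(0 < b < 1 for b in betas):
            raise ValueError("betas must lie in (0, 1)")
        self.convs = model.convs()
        self.lr, self.betas, self.eps = lr, betas, eps
        self.t = 0
        self.m = [np.zeros_like(a) for c in self.convs for a in (c.W, c.b)]
        self.v = [np.zeros_like(a) for c in self.convs for a in (c.W, c.b)]

    def step(self) -> None:
        b1, b2 = self.betas
        self.t += 1
        i = 0
        for c in self.convs:
            for w, g in ((c.W, c.dW), (c.b, c.db)):
                self.m[i] = b1 * self.m[i] + (1 - b1) * g
                self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
                mhat = self.m[i] / (1 - b1**self.t)
                vhat = self.v[i] / (1 - b2**self.t)
                w -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(w.dtype)
                i += 1
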