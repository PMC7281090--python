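"""A compact U-Net implemented on numpy + numba.

The segmentation task here — dark achromatic blobs against a pink
counterstain — needs only a small fully-convolutional encoder/decoder,
so the network is self-contained: float32 NHWC tensors, direct 3×3
same-padding convolutions as numba-JIT kernels, 2×2 max pooling,
nearest-neighbour upsampling with skip concatenation, and a
sigmoid/binary-cross-entropy head trained with Adam.  Everything is
deterministic given the initializer seed and the batch order fed to the
training loop.

Architecture contract: ``levels`` encoder stages that double the feature
channels starting from ``base_channels`` (16 → 32 → 64 → 128 with the
defaults), a bottleneck at ``base_channels * 2**levels`` (256), and a
mirrored decoder; inputs must be divisible by ``2**levels`` per axis.
"""

from __future__ import annotations

import numba
import numpy as np

__all__ = ["UNet", "Adam", "bce_with_logits", "bce_with_logits_grad"]

_F = np.float32


# --------------------------------------------------------------------------
# numba conv kernels, NHWC layout, 3×3 same padding (input pre-padded)
# --------------------------------------------------------------------------
@numba.njit(fastmath=True, cache=True)
def _conv3_fwd(xp, w, b, out):
    n, ho, wo, f = out.shape
    c = xp.shape[3]
    for ni in range(n):
        for y in range(ho):
            for x in range(wo):
                for fi in range(f):
                    out[ni, y, x, fi] = b[fi]
                for i in range(3):
                    for j in range(3):
                        for ci in range(c):
                            v = xp[ni, y + i, x + j, ci]
                            for fi in range(f):
                                out[ni, y, x, fi] += v * w[i, j, ci, fi]


@numba.njit(fastmath=True, cache=True)
def _conv3_bwd_w(xp, dout, dw, db):
    n, ho, wo, f = dout.shape
    c = xp.shape[3]
    for ni in range(n):
        for y in range(ho):
            for x in range(wo):
                d = dout[ni, y, x]
                for fi in range(f):
                    db[fi] += d[fi]
                for i in range(3):
                    for j in range(3):
                        for ci in range(c):
                            v = xp[ni, y + i, x + j, ci]
                            for fi in range(f):
                                dw[i, j, ci, fi] += v * d[fi]


@numba.njit(fastmath=True, cache=True)
def _conv3_bwd_x(dout, w, dxp):
    n, ho, wo, f = dout.shape
    c = dxp.shape[3]
    for ni in range(n):
        for y in range(ho):
            for x in range(wo):
                d = dout[ni, y, x]
                for i in range(3):
                    for j in range(3):
                        for ci in range(c):
                            s = _F(0.0)
                            for fi in range(f):
                                s += d[fi] * w[i, j, ci, fi]
                            dxp[ni, y + i, x + j, ci] += s


def _softplus(z: np.ndarray) -> np.ndarray:
    return np.logaddexp(_F(0.0), z)


def sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))


def bce_with_logits(z: np.ndarray, y: np.ndarray, pos_weight: float = 1.0) -> float:
    """Mean binary cross-entropy on logits, numerically stable.

    ``pos_weight`` scales the loss of positive pixels, countering the
    heavy class imbalance of sparse deposit masks.
    """
    per = pos_weight * y * _softplus(-z) + (1.0 - y) * (z + _softplus(-z))
    return float(per.mean())


def bce_with_logits_grad(
    z: np.ndarray, y: np.ndarray, pos_weight: float = 1.0
) -> np.ndarray:
    s = sigmoid(z)
    return (((1.0 - y) * s - pos_weight * y * (1.0 - s)) / z.size).astype(_F)


class Conv2d:
    """3×3 (numba direct) or 1×1 (GEMM) same-padding convolution, NHWC."""

    def __init__(
        self, c_in: int, c_out: int, ksize: int, rng: np.random.Generator
    ) -> None:
        fan_in = c_in * ksize * ksize
        scale = np.sqrt(2.0 / fan_in)
        if ksize == 3:
            self.w = (rng.standard_normal((3, 3, c_in, c_out)) * scale).astype(_F)
        else:
            self.w = (rng.standard_normal((c_in, c_out)) * scale).astype(_F)
        self.b = np.zeros(c_out, dtype=_F)
        self.k = ksize
        self.c_in = c_in
        self.c_out = c_out
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray, keep: bool = True) -> np.ndarray:
        n, h, w, c = x.shape
        if self.k == 1:
            self._x = x if keep else None
            out = x.reshape(n * h * w, c) @ self.w + self.b
            return out.reshape(n, h, w, self.c_out)
        xp = np.zeros((n, h + 2, w + 2, c), dtype=_F)
        xp[:, 1 : h + 1, 1 : w + 1] = x
        self._xp = xp if keep else None
        out = np.empty((n, h, w, self.c_out), dtype=_F)
        _conv3_fwd(xp, self.w, self.b, out)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, h, w, f = dout.shape
        dout = np.ascontiguousarray(dout, dtype=_F)
        if self.k == 1:
            dflat = dout.reshape(n * h * w, f)
            xflat = self._x.reshape(n * h * w, self.c_in)
            self.dw = xflat.T @ dflat
            self.db = dflat.sum(axis=0)
            return (dflat @ self.w.T).reshape(n, h, w, self.c_in)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        _conv3_bwd_w(self._xp, dout, self.dw, self.db)
        dxp = np.zeros_like(self._xp)
        _conv3_bwd_x(dout, self.w, dxp)
        return dxp[:, 1 : h + 1, 1 : w + 1]

    @property
    def params(self):
        return [(self.w, self.dw), (self.b, self.db)]


class _ReLU:
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


def _maxpool2(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n, h, w, c = x.shape
    r = x.reshape(n, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 5, 2, 4)
    r = np.ascontiguousarray(r).reshape(n, h // 2, w // 2, c, 4)
    idx = r.argmax(axis=-1)
    out = np.take_along_axis(r, idx[..., None], axis=-1)[..., 0]
    return out, idx


def _maxpool2_backward(dout: np.ndarray, idx: np.ndarray, in_shape) -> np.ndarray:
    n, h, w, c = in_shape
    r = np.zeros((n, h // 2, w // 2, c, 4), dtype=_F)
    np.put_along_axis(r, idx[..., None], dout[..., None], axis=-1)
    r = r.reshape(n, h // 2, w // 2, c, 2, 2).transpose(0, 1, 4, 2, 5, 3)
    return np.ascontiguousarray(r).reshape(n, h, w, c)


def _upsample2(x: np.ndarray) -> np.ndarray:
    return np.repeat(np.repeat(x, 2, axis=1), 2, axis=2)


def _upsample2_backward(dout: np.ndarray) -> np.ndarray:
    n, h, w, c = dout.shape
    return dout.reshape(n, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4))


class UNet:
    """Small encoder/decoder segmenter with skip connections.

    Decoder stages upsample, reduce channels with a 1×1 convolution,
    concatenate the encoder skip, and fuse with a 3×3 convolution; the
    head is a 1×1 convolution to a single logit channel.
    """

    def __init__(self, levels: int = 4, base_channels: int = 16, seed: int = 0) -> None:
        if levels < 1 or base_channels < 1:
            raise ValueError("levels and base_channels must be >= 1")
        self.levels = levels
        self.base_channels = base_channels
        rng = np.random.default_rng(seed)
        ch = [base_channels * 2**l for l in range(levels + 1)]
        self.encoder_channels = ch[:-1]
        self.bottleneck_channels = ch[-1]

        self.enc: list[tuple[Conv2d, _ReLU, Conv2d, _ReLU]] = []
        c_prev = 3
        for l in range(levels):
            self.enc.append(
                (Conv2d(c_prev, ch[l], 3, rng), _ReLU(), Conv2d(ch[l], ch[l], 3, rng), _ReLU())
            )
            c_prev = ch[l]
        self.mid = (Conv2d(c_prev, ch[-1], 3, rng), _ReLU(), Conv2d(ch[-1], ch[-1], 3, rng), _ReLU())
        self.dec: list[tuple[Conv2d, _ReLU, Conv2d, _ReLU]] = []
        c_prev = ch[-1]
        for l in reversed(range(levels)):
            up = Conv2d(c_prev, ch[l], 1, rng)  # channel reduction after upsample
            fuse = Conv2d(2 * ch[l], ch[l], 3, rng)  # after skip concatenation
            self.dec.append((up, _ReLU(), fuse, _ReLU()))
            c_prev = ch[l]
        self.head = Conv2d(c_prev, 1, 1, rng)

    # -- plumbing -----------------------------------------------------
    def _layers(self):
        for block in self.enc + [self.mid] + self.dec:
            yield block[0]
            yield block[2]
        yield self.head

    @property
    def params(self):
        out = []
        for layer in self._layers():
            out.extend(layer.params)
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        return {f"p{i}": p.copy() for i, (p, _) in enumerate(self.params)}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, (p, _) in enumerate(self.params):
            p[...] = state[f"p{i}"]

    # -- forward / backward -------------------------------------------
    def forward(self, x: np.ndarray, keep: bool = True) -> np.ndarray:
        """Logits for an (N, H, W, 3) float32 batch; H, W divisible by 2**levels."""
        n, h, w, c = x.shape
        d = 2**self.levels
        if h % d or w % d:
            raise ValueError(f"input {h}x{w} not divisible by {d}")
        x = np.ascontiguousarray(x, dtype=_F)
        self._pool_cache = []
        skips = []
        for conv1, r1, conv2, r2 in self.enc:
            x = r2.forward(conv2.forward(r1.forward(conv1.forward(x, keep)), keep))
            skips.append(x)
            x, idx = _maxpool2(x)
            self._pool_cache.append((idx, skips[-1].shape))
        conv1, r1, conv2, r2 = self.mid
        x = r2.forward(conv2.forward(r1.forward(conv1.forward(x, keep)), keep))
        self._skip_channels = []
        for (up, r1, fuse, r2), skip in zip(self.dec, reversed(skips)):
            x = r1.forward(up.forward(_upsample2(x), keep))
            x = np.concatenate([skip, x], axis=3)
            self._skip_channels.append(skip.shape[3])
            x = r2.forward(fuse.forward(np.ascontiguousarray(x), keep))
        return self.head.forward(x, keep)[..., 0]  # (N, H, W)

    def backward(self, dlogits: np.ndarray) -> None:
        dx = self.head.backward(dlogits[..., None])
        dskips = []
        for (up, r1, fuse, r2), cs in zip(
            reversed(self.dec), reversed(self._skip_channels)
        ):
            dx = fuse.backward(r2.backward(dx))
            dskips.append(dx[..., :cs])
            dx = dx[..., cs:]
            dx = _upsample2_backward(up.backward(r1.backward(dx)))
        conv1, r1, conv2, r2 = self.mid
        dx = conv1.backward(r1.backward(conv2.backward(r2.backward(dx))))
        for (conv1, r1, conv2, r2), (idx, shape), dskip in zip(
            reversed(self.enc), reversed(self._pool_cache), reversed(dskips)
        ):
            dx = _maxpool2_backward(dx, idx, shape) + dskip
            dx = conv1.backward(r1.backward(conv2.backward(r2.backward(dx))))

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Per-pixel probabilities for an (N, H, W, 3) batch (no caching)."""
        return sigmoid(self.forward(x.astype(_F), keep=False))


class Adam:
    """Standard Adam on the network's (param, grad) pairs."""

    def __init__(
        self,
        net: UNet,
        lr: float = 2e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ) -> None:
        self.net = net
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p) for p, _ in net.params]
        self.v = [np.zeros_like(p) for p, _ in net.params]

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for (p, g), m, v in zip(self.net.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
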