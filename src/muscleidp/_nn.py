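"""Minimal NumPy neural-network core for 2D segmentation networks.

Implements exactly the layers the residual U-Net family needs — 3x3/1x1
convolution (im2col + BLAS matmul), batch normalization, PReLU, nearest
upsampling — each with a hand-written backward pass, plus the Adam optimizer.

Internally tensors are channels-last, (N, H, W, C): the im2col gather then
reads contiguous channel blocks and the matmul writes the output layout
directly, which is what keeps single-core training tractable. Everything is
float32; layers cache what their backward pass needs, so a forward must
precede each backward (single-use tape discipline). Gradients are verified
against central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Param", "Conv2d", "BatchNorm2d", "PReLU", "Upsample2x", "Adam"]


class Param:
    """A trainable tensor with its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad.fill(0.0)


class Conv2d:
    """2D convolution, 'same' padding for odd kernels, optional stride.

    Layout is (N, H, W, C); the weight is (cout, k*k*cin) with the k x k
    taps outermost so each tap reads a contiguous channel block.
    He-uniform initialization.
    """

    def __init__(self, cin: int, cout: int, k: int = 3, stride: int = 1, rng=None):
        rng = rng or np.random.default_rng()
        fan_in = cin * k * k
        bound = float(np.sqrt(6.0 / fan_in))
        self.w = Param(rng.uniform(-bound, bound, size=(cout, k * k * cin)))
        self.b = Param(np.zeros(cout))
        self.k, self.stride, self.cin, self.cout = k, stride, cin, cout
        self.pad = (k - 1) // 2
        self._cache = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        n, h, w, c = x.shape
        k, s, p = self.k, self.stride, self.pad
        if k == 1:
            ho, wo = (h + s - 1) // s, (w + s - 1) // s
            cols = np.ascontiguousarray(x[:, ::s, ::s, :]).reshape(n * ho * wo, c)
        else:
            xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0))) if p else x
            win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(1, 2))
            win = win[:, ::s, ::s]  # (N, Ho, Wo, C, k, k)
            ho, wo = win.shape[1], win.shape[2]
            cols = np.ascontiguousarray(
                win.transpose(0, 1, 2, 4, 5, 3), dtype=np.float32
            ).reshape(n * ho * wo, k * k * c)
        out = cols @ self.w.value.T + self.b.value
        self._cache = (cols, x.shape, ho, wo)
        return out.reshape(n, ho, wo, self.cout)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        cols, xshape, ho, wo = self._cache
        n, h, w, c = xshape
        k, s, p = self.k, self.stride, self.pad
        g2 = gout.reshape(n * ho * wo, self.cout)
        self.w.grad += g2.T @ cols
        self.b.grad += g2.sum(axis=0)
        gcols = g2 @ self.w.value
        if k == 1:
            gx = np.zeros(xshape, dtype=np.float32)
            gx[:, ::s, ::s, :] = gcols.reshape(n, ho, wo, c)
            return gx
        gcols = gcols.reshape(n, ho, wo, k, k, c)
        gxp = np.zeros((n, h + 2 * p, w + 2 * p, c), dtype=np.float32)
        for i in range(k):
            for j in range(k):
                gxp[:, i : i + s * ho : s, j : j + s * wo : s, :] += gcols[:, :, :, i, j, :]
        return gxp[:, p : p + h, p : p + w, :] if p else gxp


class BatchNorm2d:
    """Per-channel batch normalization with running statistics for eval."""

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(c))
        self.beta = Param(np.zeros(c))
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.momentum, self.eps = momentum, eps
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        if training:
            mean = x.mean(axis=(0, 1, 2))
            var = x.var(axis=(0, 1, 2))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps).astype(np.float32)
        xhat = (x - mean) / std
        self._cache = (xhat, std, training)
        return self.gamma.value * xhat + self.beta.value

    def backward(self, gout: np.ndarray) -> np.ndarray:
        xhat, std, training = self._cache
        self.gamma.grad += (gout * xhat).sum(axis=(0, 1, 2))
        self.beta.grad += gout.sum(axis=(0, 1, 2))
        g = gout * self.gamma.value
        if not training:
            return g / std
        n, h, w, _ = gout.shape
        m = n * h * w
        gsum = g.sum(axis=(0, 1, 2))
        gxhat_sum = (g * xhat).sum(axis=(0, 1, 2))
        return (g - gsum / m - xhat * (gxhat_sum / m)) / std


class PReLU:
    """Parametric rectified linear unit with one learnable slope per channel."""

    def __init__(self, c: int, init: float = 0.25):
        self.a = Param(np.full(c, init))
        self._cache = None

    def params(self):
        return [self.a]

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        pos = np.maximum(x, 0.0)
        neg = np.minimum(x, 0.0)
        self._cache = (x, neg)
        return pos + self.a.value * neg

    def backward(self, gout: np.ndarray) -> np.ndarray:
        x, neg = self._cache
        self.a.grad += (gout * neg).sum(axis=(0, 1, 2))
        return np.where(x > 0, gout, gout * self.a.value)


class Upsample2x:
    """Nearest-neighbour x2 upsampling; backward sums each 2x2 block."""

    def params(self):
        return []

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        return x.repeat(2, axis=1).repeat(2, axis=2)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        n, h, w, c = gout.shape
        return gout.reshape(n, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4))


class Adam:
    """Adam optimizer over a flat parameter list."""

    def __init__(self, params, lr=1e-4, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1**self.t
        bias2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad**2
            p.value -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)


def softmax_channels(z: np.ndarray) -> np.ndarray:
    """Softmax over the trailing (channel) axis of an NHWC tensor."""
    zmax = z.max(axis=-1, keepdims=True)
    e = np.exp(z - zmax)
    return e / e.sum(axis=-1, keepdims=True)
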