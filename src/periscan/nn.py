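"""Minimal CPU neural-network core with manual backpropagation.

Implements exactly the layer vocabulary the two radiograph models need
(2-D convolution with optional channel groups, batch normalization,
cross-channel local response normalization, leaky/plain ReLU, max pooling
with asymmetric padding, dropout, fully connected layers) plus stochastic
gradient descent with momentum and a softmax cross-entropy head.

Conventions: activations are ``(N, C, H, W)`` arrays; fully connected
layers consume ``(N, D)``. All layers expose ``forward(x, train)``,
``backward(grad)`` and ``out_shape((C, H, W))`` so a model's activation
shapes can be audited without allocating activations.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Layer",
    "Conv2d",
    "BatchNorm2d",
    "LeakyReLU",
    "ReLU",
    "LRN",
    "MaxPool2d",
    "Dropout",
    "Flatten",
    "Dense",
    "Sequential",
    "SGDM",
    "sigmoid",
    "softmax",
    "softmax_cross_entropy",
]


class Param:
    """A trainable tensor and its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def out_shape(self, shape: tuple) -> tuple:
        return shape


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy over a batch; returns (loss, dloss/dlogits)."""
    n = logits.shape[0]
    p = softmax(logits, axis=1)
    eps = 1e-12
    loss = -np.log(p[np.arange(n), labels] + eps).mean()
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    return float(loss), grad / n


# ---------------------------------------------------------------------------
# convolution


def _windows(xp: np.ndarray, k: int, s: int) -> np.ndarray:
    """Sliding k×k windows of a padded (N,C,H,W) input, stride s.

    Returns a view of shape (N, C, Ho, Wo, k, k).
    """
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    return win[:, :, ::s, ::s]


class Conv2d(Layer):
    """2-D convolution (cross-correlation), optional channel groups.

    ``padding`` may be an int or ``"same"`` (odd kernels, stride 1 intent;
    with stride > 1 it still pads (k-1)//2 per side).
    """

    def __init__(self, in_ch, out_ch, kernel, stride=1, padding=0, groups=1,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        if in_ch % groups or out_ch % groups:
            raise ValueError("channels must divide groups")
        self.in_ch, self.out_ch, self.k = in_ch, out_ch, kernel
        self.s = stride
        self.p = (kernel - 1) // 2 if padding == "same" else int(padding)
        self.g = groups
        rng = rng or np.random.default_rng(0)
        fan_in = (in_ch // groups) * kernel * kernel
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                       size=(out_ch, in_ch // groups, kernel, kernel))
        self.w = Param(w.astype(dtype))
        self.b = Param(np.zeros(out_ch, dtype=dtype))

    def params(self):
        return [self.w, self.b]

    def out_shape(self, shape):
        c, h, w = shape
        ho = (h + 2 * self.p - self.k) // self.s + 1
        wo = (w + 2 * self.p - self.k) // self.s + 1
        return (self.out_ch, ho, wo)

    def forward(self, x, train=False):
        n = x.shape[0]
        xp = np.pad(x, ((0, 0), (0, 0), (self.p,) * 2, (self.p,) * 2)) if self.p else x
        self._xp_shape = xp.shape
        win = _windows(xp, self.k, self.s)  # (N,C,Ho,Wo,k,k)
        ho, wo = win.shape[2], win.shape[3]
        cg = self.in_ch // self.g
        og = self.out_ch // self.g
        out = np.empty((n, self.out_ch, ho, wo), dtype=x.dtype)
        self._cols = []
        wmat = self.w.value.reshape(self.out_ch, -1)
        for gi in range(self.g):
            cols = win[:, gi * cg:(gi + 1) * cg].transpose(0, 2, 3, 1, 4, 5)
            cols = np.ascontiguousarray(cols).reshape(n * ho * wo, cg * self.k * self.k)
            self._cols.append(cols)
            o = cols @ wmat[gi * og:(gi + 1) * og].T  # (NHW, og)
            out[:, gi * og:(gi + 1) * og] = o.reshape(n, ho, wo, og).transpose(0, 3, 1, 2)
        out += self.b.value[None, :, None, None]
        self._hw = (ho, wo)
        return out

    def backward(self, grad):
        n = grad.shape[0]
        ho, wo = self._hw
        cg = self.in_ch // self.g
        og = self.out_ch // self.g
        k, s, p = self.k, self.s, self.p
        dxp = np.zeros(self._xp_shape, dtype=grad.dtype)
        self.b.grad += grad.sum(axis=(0, 2, 3))
        for gi in range(self.g):
            dout = grad[:, gi * og:(gi + 1) * og].transpose(0, 2, 3, 1)
            dout = np.ascontiguousarray(dout).reshape(n * ho * wo, og)
            dw = dout.T @ self._cols[gi]  # (og, cg*k*k)
            self.w.grad[gi * og:(gi + 1) * og] += dw.reshape(og, cg, k, k)
            dcols = dout @ self.w.value[gi * og:(gi + 1) * og].reshape(og, -1)
            dcols = dcols.reshape(n, ho, wo, cg, k, k)
            tgt = dxp[:, gi * cg:(gi + 1) * cg]
            for u in range(k):
                for v in range(k):
                    tgt[:, :, u:u + s * ho:s, v:v + s * wo:s] += \
                        dcols[:, :, :, :, u, v].transpose(0, 3, 1, 2)
        self._cols = None
        if p:
            return dxp[:, :, p:-p, p:-p]
        return dxp


class BatchNorm2d(Layer):
    def __init__(self, ch, momentum=0.1, eps=1e-5, dtype=np.float32):
        self.ch, self.momentum, self.eps = ch, momentum, eps
        self.gamma = Param(np.ones(ch, dtype=dtype))
        self.beta = Param(np.zeros(ch, dtype=dtype))
        self.running_mean = np.zeros(ch, dtype=dtype)
        self.running_var = np.ones(ch, dtype=dtype)

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train=False):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mean
            self.running_var = (1 - m) * self.running_var + m * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        self._xhat, self._inv, self._train = xhat, inv, train
        return self.gamma.value[None, :, None, None] * xhat + \
            self.beta.value[None, :, None, None]

    def backward(self, grad):
        xhat, inv = self._xhat, self._inv
        self.gamma.grad += (grad * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += grad.sum(axis=(0, 2, 3))
        g = grad * self.gamma.value[None, :, None, None]
        if not self._train:
            return g * inv[None, :, None, None]
        n, _, h, w = grad.shape
        m = n * h * w
        sg = g.sum(axis=(0, 2, 3))[None, :, None, None]
        sgx = (g * xhat).sum(axis=(0, 2, 3))[None, :, None, None]
        dx = (g - sg / m - xhat * sgx / m) * inv[None, :, None, None]
        return dx


class LeakyReLU(Layer):
    def __init__(self, alpha=0.1):
        self.alpha = alpha

    def forward(self, x, train=False):
        self._mask = x > 0
        return np.where(self._mask, x, self.alpha * x)

    def backward(self, grad):
        return np.where(self._mask, grad, self.alpha * grad)


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


def _channel_window_sum(t: np.ndarray, n: int) -> np.ndarray:
    """Sum of t over a centred window of n channels (clipped at edges)."""
    c = t.shape[1]
    half = n // 2
    cs = np.concatenate(
        [np.zeros_like(t[:, :1]), np.cumsum(t, axis=1)], axis=1)
    lo = np.maximum(0, np.arange(c) - half)
    hi = np.minimum(c, np.arange(c) + half + 1)
    return cs[:, hi] - cs[:, lo]


class LRN(Layer):
    """Cross-channel local response normalization (AlexNet-style)."""

    def __init__(self, n=5, alpha=1e-4, beta=0.75, k=2.0):
        self.n, self.alpha, self.beta, self.k = n, alpha, beta, k

    def forward(self, x, train=False):
        s = _channel_window_sum(x * x, self.n)
        den = self.k + (self.alpha / self.n) * s
        self._x, self._den = x, den
        return x * den ** (-self.beta)

    def backward(self, grad):
        x, den = self._x, self._den
        t = _channel_window_sum(grad * x * den ** (-self.beta - 1), self.n)
        return grad * den ** (-self.beta) - \
            (2.0 * self.alpha * self.beta / self.n) * x * t


class MaxPool2d(Layer):
    """Max pooling; ``padding`` is (top, bottom, left, right), filled -inf."""

    def __init__(self, kernel, stride=None, padding=(0, 0, 0, 0)):
        self.k = kernel
        self.s = stride or kernel
        self.pad = padding

    def out_shape(self, shape):
        c, h, w = shape
        pt, pb, pl, pr = self.pad
        ho = (h + pt + pb - self.k) // self.s + 1
        wo = (w + pl + pr - self.k) // self.s + 1
        return (c, ho, wo)

    def forward(self, x, train=False):
        pt, pb, pl, pr = self.pad
        if any(self.pad):
            xp = np.pad(x, ((0, 0), (0, 0), (pt, pb), (pl, pr)),
                        constant_values=-np.inf)
        else:
            xp = x
        self._xp_shape = xp.shape
        win = _windows(xp, self.k, self.s)
        n, c, ho, wo = win.shape[:4]
        flat = win.reshape(n, c, ho, wo, self.k * self.k)
        self._idx = flat.argmax(axis=-1)
        out = np.take_along_axis(flat, self._idx[..., None], axis=-1)[..., 0]
        self._hw = (ho, wo)
        return out

    def backward(self, grad):
        pt, pb, pl, pr = self.pad
        ho, wo = self._hw
        dxp = np.zeros(self._xp_shape, dtype=grad.dtype)
        k, s = self.k, self.s
        for t in range(k * k):
            u, v = divmod(t, k)
            sel = (self._idx == t) * grad
            dxp[:, :, u:u + s * ho:s, v:v + s * wo:s] += sel
        h, w = dxp.shape[2] - pt - pb, dxp.shape[3] - pl - pr
        return dxp[:, :, pt:pt + h, pl:pl + w]


class Dropout(Layer):
    def __init__(self, p=0.5, rng: np.random.Generator | None = None):
        self.p = p
        self.rng = rng or np.random.default_rng(0)

    def forward(self, x, train=False):
        if not train or self.p == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, grad):
        if self._mask is None:
            return grad
        return grad * self._mask


class Flatten(Layer):
    def out_shape(self, shape):
        return (int(np.prod(shape)),)

    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, d_in, d_out, rng: np.random.Generator | None = None,
                 dtype=np.float32):
        rng = rng or np.random.default_rng(0)
        w = rng.normal(0.0, np.sqrt(2.0 / d_in), size=(d_in, d_out))
        self.w = Param(w.astype(dtype))
        self.b = Param(np.zeros(d_out, dtype=dtype))

    def params(self):
        return [self.w, self.b]

    def out_shape(self, shape):
        return (self.w.value.shape[1],)

    def forward(self, x, train=False):
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, grad):
        self.w.grad += self._x.T @ grad
        self.b.grad += grad.sum(axis=0)
        return grad @ self.w.value.T


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self):
        out = []
        for lay in self.layers:
            out.extend(lay.params())
        return out

    def forward(self, x, train=False):
        for lay in self.layers:
            x = lay.forward(x, train=train)
        return x

    def backward(self, grad):
        for lay in reversed(self.layers):
            grad = lay.backward(grad)
        return grad

    def out_shape(self, shape):
        for lay in self.layers:
            shape = lay.out_shape(shape)
        return shape

    def activation_shapes(self, shape):
        shapes = []
        for lay in self.layers:
            shape = lay.out_shape(shape)
            shapes.append(shape)
        return shapes


class SGDM:
    """Stochastic gradient descent with classical momentum.

    ``max_grad_norm`` rescales the global gradient norm when it exceeds
    the bound, which keeps the squared-error detection objective stable
    in float32.
    """

    def __init__(self, params: list[Param], lr: float, momentum: float = 0.9,
                 max_grad_norm: float | None = 10.0):
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self.max_grad_norm = max_grad_norm
        self.vel = [np.zeros_like(p.value) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self, lr: float | None = None):
        lr = self.lr if lr is None else lr
        scale = 1.0
        if self.max_grad_norm is not None:
            total = np.sqrt(sum(float((p.grad.astype(np.float64) ** 2).sum())
                                for p in self.params))
            if total > self.max_grad_norm:
                scale = self.max_grad_norm / total
        for p, v in zip(self.params, self.vel):
            v *= self.momentum
            v -= lr * scale * p.grad
            p.value += v
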