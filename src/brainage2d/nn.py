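"""Minimal neural-network layers with hand-written backpropagation.

Implements exactly the operations the projection networks need: 3x3
same-padding convolution, batch normalization, ReLU, dropout, 2x2 max
pooling (ceil mode), global mean pooling, dense layers, MSE loss and the
Adam optimizer, all on float32 NumPy arrays.

Layers are functional: ``forward`` returns ``(output, cache)`` and
``backward`` consumes the cache and *accumulates* into ``Param.grad``.
This makes weight sharing trivial — applying the same layer object to
several inputs simply sums the parameter gradients, which is how the
iso (shared-stack) models are trained.

Image tensors are channels-last, ``(N, H, W, C)``: with one CPU and a
fast BLAS the engine is memory-bound, and NHWC lets the convolution run
as one large matrix product over the padded grid with no per-pixel
gather and no layout transposes between layers. Feature tensors are
``(N, D)``.
"""

from __future__ import annotations

import numpy as np


class Param:
    """A trainable tensor with an accumulated gradient."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = np.ascontiguousarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)
        self.name = name

    @property
    def size(self) -> int:
        return self.value.size

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


def glorot_uniform(rng: np.random.Generator, shape, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


class Layer:
    """Base class; stateless layers only need ``forward``/``backward``."""

    def params(self) -> list[Param]:
        return []

    def forward(self, x, *, training: bool, rng: np.random.Generator | None = None):
        raise NotImplementedError

    def backward(self, grad, cache):
        raise NotImplementedError


class Conv2D(Layer):
    """3x3 (or kxk) convolution, stride 1, zero same-padding, NHWC.

    The kernel is stored as ``(k, k, C_in, F)``. The forward pass runs
    one matrix product of the whole padded grid against all k*k taps at
    once and accumulates shifted views; backward mirrors it. ``bias=False``
    is used for convolutions immediately followed by batch
    normalization, where a bias would be redundant.
    """

    def __init__(self, c_in: int, c_out: int, *, kernel: int = 3, bias: bool = True,
                 rng: np.random.Generator | None = None, name: str = "conv"):
        rng = rng or np.random.default_rng()
        k = kernel
        fan_in, fan_out = c_in * k * k, c_out * k * k
        w = glorot_uniform(rng, (k, k, c_in, c_out), fan_in, fan_out)
        self.kernel = k
        self.c_in, self.c_out = c_in, c_out
        self.W = Param(w, f"{name}.W")
        self.b = Param(np.zeros(c_out, np.float32), f"{name}.b") if bias else None

    def params(self):
        return [self.W] + ([self.b] if self.b is not None else [])

    def _w2(self) -> np.ndarray:
        # (k, k, C, F) tap-major -> (C, k*k*F)
        return np.ascontiguousarray(self.W.value.transpose(2, 0, 1, 3)
                                    ).reshape(self.c_in, -1)

    def forward(self, x, *, training=False, rng=None):
        k, p = self.kernel, self.kernel // 2
        n, h, w, c = x.shape
        f = self.c_out
        hp, wp = h + 2 * p, w + 2 * p
        xp = np.zeros((n, hp, wp, c), np.float32)
        xp[:, p:p + h, p:p + w, :] = x
        full = (xp.reshape(-1, c) @ self._w2()).reshape(n, hp, wp, k, k, f)
        out = np.zeros((n, h, w, f), np.float32)
        for dy in range(k):
            for dx in range(k):
                out += full[:, dy:dy + h, dx:dx + w, dy, dx, :]
        if self.b is not None:
            out += self.b.value
        return out, (xp, (h, w))

    def backward(self, grad, cache):
        xp, (h, w) = cache
        k, p = self.kernel, self.kernel // 2
        n = xp.shape[0]
        c, f = self.c_in, self.c_out
        hp, wp = h + 2 * p, w + 2 * p
        if self.b is not None:
            self.b.grad += grad.sum(axis=(0, 1, 2))
        gfull = np.zeros((n, hp, wp, k, k, f), np.float32)
        for dy in range(k):
            for dx in range(k):
                gfull[:, dy:dy + h, dx:dx + w, dy, dx, :] = grad
        gflat = gfull.reshape(n * hp * wp, -1)
        wgrad = xp.reshape(-1, c).T @ gflat               # (C, k*k*F)
        self.W.grad += wgrad.reshape(c, k, k, f).transpose(1, 2, 0, 3)
        gxp = (gflat @ self._w2().T).reshape(n, hp, wp, c)
        return np.ascontiguousarray(gxp[:, p:p + h, p:p + w, :])


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, *, bias: bool = True,
                 rng: np.random.Generator | None = None, name: str = "dense"):
        rng = rng or np.random.default_rng()
        w = glorot_uniform(rng, (d_in, d_out), d_in, d_out)
        self.d_in, self.d_out = d_in, d_out
        self.W = Param(w, f"{name}.W")
        self.b = Param(np.zeros(d_out, np.float32), f"{name}.b") if bias else None

    def params(self):
        return [self.W] + ([self.b] if self.b is not None else [])

    def forward(self, x, *, training=False, rng=None):
        out = x @ self.W.value
        if self.b is not None:
            out = out + self.b.value
        return out, x

    def backward(self, grad, cache):
        x = cache
        self.W.grad += x.T @ grad
        if self.b is not None:
            self.b.grad += grad.sum(axis=0)
        return grad @ self.W.value.T


class BatchNorm2d(Layer):
    """Per-channel batch normalization over (N, H, W) with running stats."""

    def __init__(self, c: int, *, momentum: float = 0.1, eps: float = 1e-5, name: str = "bn"):
        self.c = c
        self.eps = eps
        self.momentum = momentum
        self.gamma = Param(np.ones(c, np.float32), f"{name}.gamma")
        self.beta = Param(np.zeros(c, np.float32), f"{name}.beta")
        self.running_mean = np.zeros(c, np.float32)
        self.running_var = np.ones(c, np.float32)

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, *, training=False, rng=None):
        if training:
            mean = x.mean(axis=(0, 1, 2))
            var = x.var(axis=(0, 1, 2))
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean + m * mean).astype(np.float32)
            self.running_var = ((1 - m) * self.running_var + m * var).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        inv = (1.0 / np.sqrt(var + self.eps)).astype(np.float32)
        xhat = (x - mean) * inv
        out = self.gamma.value * xhat + self.beta.value
        return out.astype(np.float32), (xhat, inv, training, x.shape)

    def backward(self, grad, cache):
        xhat, inv, training, shape = cache
        n_eff = shape[0] * shape[1] * shape[2]
        self.gamma.grad += (grad * xhat).sum(axis=(0, 1, 2))
        self.beta.grad += grad.sum(axis=(0, 1, 2))
        g = grad * self.gamma.value
        if not training:
            return (g * inv).astype(np.float32)
        dxhat_sum = g.sum(axis=(0, 1, 2))
        dxhat_xhat_sum = (g * xhat).sum(axis=(0, 1, 2))
        gx = g - (dxhat_sum + xhat * dxhat_xhat_sum) / n_eff
        return (gx * inv).astype(np.float32)


class ReLU(Layer):
    def forward(self, x, *, training=False, rng=None):
        mask = x > 0
        return x * mask, mask

    def backward(self, grad, cache):
        return grad * cache


class Dropout(Layer):
    """Inverted dropout; identity when not training or when rate is 0."""

    def __init__(self, rate: float):
        self.rate = float(rate)

    def forward(self, x, *, training=False, rng=None):
        if not training or self.rate <= 0.0:
            return x, None
        if rng is None:
            raise ValueError("dropout in training mode needs an rng")
        keep = 1.0 - self.rate
        mask = (rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * mask, mask

    def backward(self, grad, cache):
        if cache is None:
            return grad
        return grad * cache


class MaxPool2(Layer):
    """2x2 max pooling, stride 2, ceil mode (odd extents padded with -inf),
    NHWC. Ties route the gradient to the first maximum (argmax order)."""

    def forward(self, x, *, training=False, rng=None):
        n, h, w, c = x.shape
        ph, pw = (-h) % 2, (-w) % 2
        if ph or pw:
            x = np.pad(x, ((0, 0), (0, ph), (0, pw), (0, 0)),
                       constant_values=-np.inf)
        hh, ww = x.shape[1] // 2, x.shape[2] // 2
        flat = np.ascontiguousarray(
            x.reshape(n, hh, 2, ww, 2, c).transpose(0, 1, 3, 5, 2, 4)
        ).reshape(n, hh, ww, c, 4)
        arg = flat.argmax(axis=-1)
        out = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]
        return np.ascontiguousarray(out), (arg, (h, w))

    def backward(self, grad, cache):
        arg, (h, w) = cache
        n, hh, ww, c = arg.shape
        g4 = np.zeros((n, hh, ww, c, 4), np.float32)
        np.put_along_axis(g4, arg[..., None], grad[..., None], axis=-1)
        g = g4.reshape(n, hh, ww, c, 2, 2).transpose(0, 1, 4, 2, 5, 3)
        g = g.reshape(n, hh * 2, ww * 2, c)[:, :h, :w, :]
        return np.ascontiguousarray(g)


class GlobalMeanPool(Layer):
    """Mean over the spatial extent: (N, H, W, C) -> (N, C)."""

    def forward(self, x, *, training=False, rng=None):
        return x.mean(axis=(1, 2)), x.shape

    def backward(self, grad, cache):
        n, h, w, c = cache
        return np.broadcast_to(grad[:, None, None, :] / (h * w), (n, h, w, c)
                               ).astype(np.float32)


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = list(layers)

    def params(self):
        out = []
        for lay in self.layers:
            out.extend(lay.params())
        return out

    def forward(self, x, *, training=False, rng=None):
        caches = []
        for lay in self.layers:
            x, cache = lay.forward(x, training=training, rng=rng)
            caches.append(cache)
        return x, caches

    def backward(self, grad, caches):
        for lay, cache in zip(reversed(self.layers), reversed(caches)):
            grad = lay.backward(grad, cache)
        return grad


def mse_loss(pred: np.ndarray, target: np.ndarray):
    """Mean squared error and its gradient with respect to ``pred``."""
    diff = pred.astype(np.float64) - target.astype(np.float64)
    loss = float(np.mean(diff ** 2))
    grad = (2.0 / diff.size) * diff
    return loss, grad.astype(np.float32)


class Adam:
    """Adam optimizer over a list of unique :class:`Param` objects."""

    def __init__(self, params: list[Param], lr: float = 0.003,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        # deduplicate while preserving order (shared stacks pass the same Param thrice)
        seen: dict[int, Param] = {}
        for p in params:
            seen.setdefault(id(p), p)
        self.params = list(seen.values())
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()

    def step(self):
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.value -= (self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)).astype(np.float32)
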