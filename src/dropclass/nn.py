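"""Minimal pure-numpy convolutional network toolkit.

Implements exactly the pieces the droplet classifier needs — im2col
convolutions, batch normalization, ReLU, max/global-average pooling, dense
layers, residual (basic and bottleneck) blocks, softmax cross-entropy and
mini-batch SGD — with explicit forward/backward passes in float32.

Design notes
------------
* Gradients flow through hand-written ``backward`` methods; each layer
  caches whatever its backward pass needs during ``forward``.
* The cross-entropy loss is *summed* over the mini-batch (classical
  empirical-risk mini-batch SGD), so the effective step size scales with
  the batch size; see the methods note for why this convention is used.
* All initialization draws from a caller-supplied ``numpy.random.Generator``
  so a fixed seed gives deterministic initial weights.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


class Param:
    __slots__ = ("data", "grad", "vel")

    def __init__(self, data):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad = np.zeros_like(self.data)
        self.vel = np.zeros_like(self.data)


class Module:
    """Base class: tracks child modules and owned parameters."""

    def __init__(self):
        self._children: list[Module] = []
        self.params: list[Param] = []

    def add(self, child: "Module") -> "Module":
        self._children.append(child)
        return child

    def all_params(self) -> list[Param]:
        out = list(self.params)
        for c in self._children:
            out.extend(c.all_params())
        return out

    def state_arrays(self) -> list[np.ndarray]:
        """Every persistent array (weights + e.g. BN running stats), in a
        deterministic traversal order, for checkpointing."""
        out = [p.data for p in self.params] + list(self._extra_state())
        for c in self._children:
            out.extend(c.state_arrays())
        return out

    def load_state_arrays(self, arrays: list[np.ndarray], pos: int = 0) -> int:
        for p in self.params:
            p.data[...] = arrays[pos]
            pos += 1
        pos = self._load_extra_state(arrays, pos)
        for c in self._children:
            pos = c.load_state_arrays(arrays, pos)
        return pos

    def _extra_state(self):
        return ()

    def _load_extra_state(self, arrays, pos):
        return pos

    def forward(self, x, train: bool = False):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout):  # pragma: no cover - interface
        raise NotImplementedError


def _out_size(h, k, stride, pad):
    return (h + 2 * pad - k) // stride + 1


def im2col(x, kh, kw, stride, pad, fill=0.0):
    """(N, C, H, W) -> (N, C*kh*kw, OH*OW) patch matrix."""
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)), constant_values=fill)
    oh = _out_size(h, kh, stride, pad)
    ow = _out_size(w, kw, stride, pad)
    cols = np.empty((n, c, kh, kw, oh, ow), dtype=x.dtype)
    for i in range(kh):
        for j in range(kw):
            cols[:, :, i, j] = x[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride]
    return cols.reshape(n, c * kh * kw, oh * ow), (oh, ow)


def col2im(dcols, x_shape, kh, kw, stride, pad):
    """Adjoint of im2col: scatter-add patches back onto the input grid."""
    n, c, h, w = x_shape
    oh = _out_size(h, kh, stride, pad)
    ow = _out_size(w, kw, stride, pad)
    dcols = dcols.reshape(n, c, kh, kw, oh, ow)
    dx = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=dcols.dtype)
    for i in range(kh):
        for j in range(kw):
            dx[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride] += dcols[:, :, i, j]
    return dx[:, :, pad : pad + h, pad : pad + w] if pad else dx


class Conv2d(Module):
    def __init__(self, in_ch, out_ch, k, stride=1, pad=0, rng=None, bias=False):
        super().__init__()
        self.in_ch, self.out_ch, self.k, self.stride, self.pad = in_ch, out_ch, k, stride, pad
        fan_in = in_ch * k * k
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_ch, fan_in))
        self.w = Param(w)
        self.params = [self.w]
        self.b = None
        if bias:
            self.b = Param(np.zeros(out_ch))
            self.params.append(self.b)

    def forward(self, x, train=False):
        self._x_shape = x.shape
        cols, (oh, ow) = im2col(x, self.k, self.k, self.stride, self.pad)
        self._cols = cols
        out = np.matmul(self.w.data, cols)  # (N, out_ch, L)
        if self.b is not None:
            out += self.b.data[None, :, None]
        return out.reshape(x.shape[0], self.out_ch, oh, ow)

    def backward(self, dout):
        n = dout.shape[0]
        dflat = dout.reshape(n, self.out_ch, -1)
        self.w.grad += np.matmul(dflat, self._cols.transpose(0, 2, 1)).sum(axis=0)
        if self.b is not None:
            self.b.grad += dflat.sum(axis=(0, 2))
        dcols = np.matmul(self.w.data.T, dflat)
        self._cols = None
        return col2im(dcols, self._x_shape, self.k, self.k, self.stride, self.pad)


class BatchNorm2d(Module):
    def __init__(self, ch, momentum=0.1, eps=1e-5):
        super().__init__()
        self.gamma = Param(np.ones(ch))
        self.beta = Param(np.zeros(ch))
        self.params = [self.gamma, self.beta]
        self.running_mean = np.zeros(ch, dtype=DTYPE)
        self.running_var = np.ones(ch, dtype=DTYPE)
        self.momentum, self.eps = momentum, eps
        self._seen_batch = False

    def _extra_state(self):
        return (self.running_mean, self.running_var)

    def _load_extra_state(self, arrays, pos):
        self.running_mean[...] = arrays[pos]
        self.running_var[...] = arrays[pos + 1]
        self._seen_batch = True
        return pos + 2

    def forward(self, x, train=False):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            if not self._seen_batch:
                # warm-start the running stats at the first batch: with the
                # short training schedules used here, an EMA started from
                # (0, 1) would still be far from the true activation scale
                # at the end of training
                self.running_mean[...] = mean
                self.running_var[...] = var
                self._seen_batch = True
            else:
                self.running_mean += self.momentum * (mean - self.running_mean)
                self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps).astype(DTYPE)
        self._xhat = (x - mean[None, :, None, None]) / self._std[None, :, None, None]
        self._train = train
        return self.gamma.data[None, :, None, None] * self._xhat + self.beta.data[None, :, None, None]

    def backward(self, dout):
        xhat = self._xhat
        axes = (0, 2, 3)
        self.gamma.grad += (dout * xhat).sum(axis=axes)
        self.beta.grad += dout.sum(axis=axes)
        g = (self.gamma.data / self._std)[None, :, None, None]
        if not self._train:
            return dout * g
        dxhat = dout * self.gamma.data[None, :, None, None]
        term = (
            dxhat
            - dxhat.mean(axis=axes, keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=axes, keepdims=True)
        )
        self._xhat = None
        return term / self._std[None, :, None, None]


class ReLU(Module):
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class MaxPool2d(Module):
    def __init__(self, k=2, stride=2, pad=0):
        super().__init__()
        self.k, self.stride, self.pad = k, stride, pad

    def forward(self, x, train=False):
        self._x_shape = x.shape
        n, c, h, w = x.shape
        cols, (oh, ow) = im2col(
            x.reshape(n * c, 1, h, w), self.k, self.k, self.stride, self.pad, fill=-np.inf
        )
        self._argmax = cols.argmax(axis=1)
        out = np.take_along_axis(cols, self._argmax[:, None, :], axis=1)[:, 0, :]
        return out.reshape(n, c, oh, ow)

    def backward(self, dout):
        n, c, h, w = self._x_shape
        dflat = dout.reshape(n * c, -1)
        dcols = np.zeros((n * c, self.k * self.k, dflat.shape[1]), dtype=dout.dtype)
        np.put_along_axis(dcols, self._argmax[:, None, :], dflat[:, None, :], axis=1)
        dx = col2im(dcols, (n * c, 1, h, w), self.k, self.k, self.stride, self.pad)
        return dx.reshape(n, c, h, w)


class GlobalAvgPool(Module):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout):
        n, c, h, w = self._shape
        return np.broadcast_to(dout[:, :, None, None], self._shape) / (h * w)


class Dense(Module):
    def __init__(self, n_in, n_out, rng):
        super().__init__()
        self.w = Param(rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out)))
        self.b = Param(np.zeros(n_out))
        self.params = [self.w, self.b]

    def forward(self, x, train=False):
        self._x = x
        return x @ self.w.data + self.b.data

    def backward(self, dout):
        self.w.grad += self._x.T @ dout
        self.b.grad += dout.sum(axis=0)
        return dout @ self.w.data.T


class Sequential(Module):
    def __init__(self, *layers):
        super().__init__()
        for layer in layers:
            self.add(layer)

    def forward(self, x, train=False):
        for layer in self._children:
            x = layer.forward(x, train)
        return x

    def backward(self, dout):
        for layer in reversed(self._children):
            dout = layer.backward(dout)
        return dout


class BasicBlock(Module):
    """Two 3x3 convolutions with an identity (or 1x1 projection) skip."""

    def __init__(self, in_ch, out_ch, stride, rng):
        super().__init__()
        self.main = self.add(
            Sequential(
                Conv2d(in_ch, out_ch, 3, stride, 1, rng),
                BatchNorm2d(out_ch),
                ReLU(),
                Conv2d(out_ch, out_ch, 3, 1, 1, rng),
                BatchNorm2d(out_ch),
            )
        )
        self.proj = None
        if stride != 1 or in_ch != out_ch:
            self.proj = self.add(
                Sequential(Conv2d(in_ch, out_ch, 1, stride, 0, rng), BatchNorm2d(out_ch))
            )
        self.relu = self.add(ReLU())

    def forward(self, x, train=False):
        main = self.main.forward(x, train)
        skip = self.proj.forward(x, train) if self.proj is not None else x
        return self.relu.forward(main + skip, train)

    def backward(self, dout):
        dsum = self.relu.backward(dout)
        dx = self.main.backward(dsum)
        dx = dx + (self.proj.backward(dsum) if self.proj is not None else dsum)
        return dx


class BottleneckBlock(Module):
    """1x1 -> 3x3 -> 1x1 (x4 expansion) residual block."""

    EXPANSION = 4

    def __init__(self, in_ch, mid_ch, stride, rng):
        super().__init__()
        out_ch = mid_ch * self.EXPANSION
        self.main = self.add(
            Sequential(
                Conv2d(in_ch, mid_ch, 1, 1, 0, rng),
                BatchNorm2d(mid_ch),
                ReLU(),
                Conv2d(mid_ch, mid_ch, 3, stride, 1, rng),
                BatchNorm2d(mid_ch),
                ReLU(),
                Conv2d(mid_ch, out_ch, 1, 1, 0, rng),
                BatchNorm2d(out_ch),
            )
        )
        self.proj = None
        if stride != 1 or in_ch != out_ch:
            self.proj = self.add(
                Sequential(Conv2d(in_ch, out_ch, 1, stride, 0, rng), BatchNorm2d(out_ch))
            )
        self.relu = self.add(ReLU())

    forward = BasicBlock.forward
    backward = BasicBlock.backward


def softmax(logits):
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(logits, labels):
    """Summed categorical cross-entropy and its gradient w.r.t. the logits.

    Returns ``(loss_sum, dlogits, probs)``.
    """
    probs = softmax(logits.astype(np.float64))
    n = len(labels)
    eps = 1e-12
    loss = -np.log(probs[np.arange(n), labels] + eps).sum()
    dlogits = probs.copy()
    dlogits[np.arange(n), labels] -= 1.0
    return float(loss), dlogits.astype(DTYPE), probs


class SGD:
    """Mini-batch stochastic gradient descent with optional momentum."""

    def __init__(self, params, lr, momentum=0.0):
        self.params, self.lr, self.momentum = list(params), lr, momentum

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0

    def step(self):
        for p in self.params:
            if self.momentum:
                p.vel = self.momentum * p.vel - self.lr * p.grad
                p.data += p.vel
            else:
                p.data -= self.lr * p.grad
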