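"""Minimal reverse-mode autodiff on numpy arrays for small 3D segmentation nets.

Feature maps are ``(C, Z, H, W)`` float32 arrays (implicit batch of one).
Convolutions are stride-1, same-padding, realized as im2col + matmul; the
backward pass folds the column gradient back with a loop over kernel
offsets. The op set is exactly what an attention U-Net needs: conv3d,
relu/sigmoid/softmax, 2x max-pool and nearest upsampling, concatenation,
broadcasting multiply/add, and reductions for the Dice loss.

Gradient correctness is guarded by finite-difference checks in the test
suite rather than by construction, so keep ops simple and explicit.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import as_strided


class Tensor:
    """An array node on the autodiff tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad=False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def _accum(self, g):
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float32, copy=True)
        else:
            self.grad += g

    def zero_grad(self):
        self.grad = None

    # -- convenience arithmetic (scalar or Tensor operands) --
    def __add__(self, other):
        return add(self, _as_tensor(other))

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, _as_tensor(other))

    __rmul__ = __mul__

    def __sub__(self, other):
        return add(self, mul(_as_tensor(other), _const(-1.0)))

    def __rsub__(self, other):
        return add(_as_tensor(other), mul(self, _const(-1.0)))

    def __truediv__(self, other):
        return div(self, _as_tensor(other))


def _const(x):
    return Tensor(np.asarray(x, dtype=np.float32))


def _as_tensor(x):
    return x if isinstance(x, Tensor) else _const(x)


def _needs(*ts):
    return any(t.requires_grad for t in ts)


def _unbroadcast(g, shape):
    """Reduce a gradient back to ``shape`` after numpy broadcasting."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def add(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data + b.data, _needs(a, b), (a, b))

    def backward(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g, a.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g, b.shape))

    out._backward = backward
    return out


def mul(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data * b.data, _needs(a, b), (a, b))

    def backward(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g * b.data, a.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g * a.data, b.shape))

    out._backward = backward
    return out


def div(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data / b.data, _needs(a, b), (a, b))

    def backward(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g / b.data, a.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(-g * a.data / (b.data**2), b.shape))

    out._backward = backward
    return out


def relu(x: Tensor) -> Tensor:
    out = Tensor(np.maximum(x.data, 0.0), x.requires_grad, (x,))

    def backward(g):
        if x.requires_grad:
            x._accum(g * (x.data > 0))

    out._backward = backward
    return out


def sigmoid(x: Tensor) -> Tensor:
    y = np.empty_like(x.data)
    pos = x.data >= 0
    y[pos] = 1.0 / (1.0 + np.exp(-x.data[pos]))
    e = np.exp(x.data[~pos])
    y[~pos] = e / (1.0 + e)
    out = Tensor(y, x.requires_grad, (x,))

    def backward(g):
        if x.requires_grad:
            x._accum(g * y * (1.0 - y))

    out._backward = backward
    return out


def softmax_channels(x: Tensor) -> Tensor:
    """Softmax over axis 0 (channels)."""
    e = np.exp(x.data - x.data.max(axis=0, keepdims=True))
    y = e / e.sum(axis=0, keepdims=True)
    out = Tensor(y, x.requires_grad, (x,))

    def backward(g):
        if x.requires_grad:
            x._accum(y * (g - (g * y).sum(axis=0, keepdims=True)))

    out._backward = backward
    return out


def tsum(x: Tensor) -> Tensor:
    out = Tensor(x.data.sum(), x.requires_grad, (x,))

    def backward(g):
        if x.requires_grad:
            x._accum(np.full(x.shape, g, dtype=np.float32))

    out._backward = backward
    return out


def _im2col(xp: np.ndarray, k: int, out_shape):
    C = xp.shape[0]
    Z, H, W = out_shape
    s = xp.strides
    view = as_strided(
        xp, shape=(C, k, k, k, Z, H, W),
        strides=(s[0], s[1], s[2], s[3], s[1], s[2], s[3]),
    )
    return np.ascontiguousarray(view).reshape(C * k**3, Z * H * W)


def conv3d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Stride-1 same-padding 3D convolution; w is (Cout, Cin, k, k, k)."""
    cout, cin, k = w.shape[0], w.shape[1], w.shape[2]
    if x.shape[0] != cin:
        raise ValueError(f"expected {cin} input channels, got {x.shape[0]}")
    p = k // 2
    spatial = x.shape[1:]
    xp = np.pad(x.data, ((0, 0),) + ((p, p),) * 3) if p else x.data
    col = _im2col(xp, k, spatial)
    wmat = w.data.reshape(cout, cin * k**3)
    y = (wmat @ col + b.data[:, None]).reshape((cout,) + spatial)
    out = Tensor(y, _needs(x, w, b), (x, w, b))
    del col  # recomputed in backward: retaining it would dominate memory

    def backward(g):
        gmat = g.reshape(cout, -1)
        if w.requires_grad:
            w._accum((gmat @ _im2col(xp, k, spatial).T).reshape(w.shape))
        if b.requires_grad:
            b._accum(gmat.sum(axis=1))
        if x.requires_grad:
            dcol = (wmat.T @ gmat).reshape((cin, k, k, k) + spatial)
            gxp = np.zeros_like(xp)
            Z, H, W = spatial
            for dz in range(k):
                for dy in range(k):
                    for dx in range(k):
                        gxp[:, dz:dz + Z, dy:dy + H, dx:dx + W] += dcol[:, dz, dy, dx]
            x._accum(gxp[:, p:p + Z, p:p + H, p:p + W] if p else gxp)

    out._backward = backward
    return out


def maxpool2(x: Tensor) -> Tensor:
    C, Z, H, W = x.shape
    if Z % 2 or H % 2 or W % 2:
        raise ValueError("maxpool2 requires even spatial dimensions")
    r = x.data.reshape(C, Z // 2, 2, H // 2, 2, W // 2, 2)
    y = r.max(axis=(2, 4, 6))
    out = Tensor(y, x.requires_grad, (x,))

    def backward(g):
        if x.requires_grad:
            yb = np.repeat(np.repeat(np.repeat(y, 2, 1), 2, 2), 2, 3)
            mask = (x.data == yb).astype(np.float32)
            counts = mask.reshape(C, Z // 2, 2, H // 2, 2, W // 2, 2).sum(
                axis=(2, 4, 6))
            cb = np.repeat(np.repeat(np.repeat(counts, 2, 1), 2, 2), 2, 3)
            gb = np.repeat(np.repeat(np.repeat(g, 2, 1), 2, 2), 2, 3)
            x._accum(gb * mask / cb)

    out._backward = backward
    return out


def upsample2(x: Tensor) -> Tensor:
    """Nearest-neighbor 2x upsampling on the three spatial axes."""
    y = np.repeat(np.repeat(np.repeat(x.data, 2, 1), 2, 2), 2, 3)
    out = Tensor(y, x.requires_grad, (x,))

    def backward(g):
        if x.requires_grad:
            C, Z, H, W = x.shape
            x._accum(g.reshape(C, Z, 2, H, 2, W, 2).sum(axis=(2, 4, 6)))

    out._backward = backward
    return out


def concat_channels(tensors) -> Tensor:
    tensors = list(tensors)
    out = Tensor(np.concatenate([t.data for t in tensors], axis=0),
                 _needs(*tensors), tuple(tensors))
    sizes = [t.shape[0] for t in tensors]

    def backward(g):
        start = 0
        for t, s in zip(tensors, sizes):
            if t.requires_grad:
                t._accum(g[start:start + s])
            start += s

    out._backward = backward
    return out


def slice_channels(x: Tensor, start: int, stop: int) -> Tensor:
    out = Tensor(x.data[start:stop], x.requires_grad, (x,))

    def backward(g):
        if x.requires_grad:
            gx = np.zeros(x.shape, dtype=np.float32)
            gx[start:stop] = g
            x._accum(gx)

    out._backward = backward
    return out


def soft_dice_loss(pred: Tensor, target: np.ndarray, eps: float = 1e-5,
                   skip_empty: bool = False) -> Tensor:
    """1 - mean over channels of soft Dice; target is a constant (C, ...) array.

    A prediction equal to the one-hot truth scores 0; its complement ~1.
    With ``skip_empty``, channels whose target is empty are excluded from the
    mean (their Dice is undefined on that sample); a patch missing a
    structure then exerts no collapse pressure on that structure's decoder.
    """
    target = np.asarray(target, dtype=np.float32)
    if target.shape != pred.shape:
        raise ValueError("prediction and target shapes must match")
    C = pred.shape[0]
    total = _const(0.0)
    used = 0
    for c in range(C):
        t = target[c:c + 1]
        t_sum = float(t.sum())
        if skip_empty and t_sum == 0.0:
            continue
        p = slice_channels(pred, c, c + 1)
        num = tsum(mul(p, _const(t))) * 2.0 + eps
        den = tsum(p) + _const(t_sum) + eps
        total = total + div(num, den)
        used += 1
    if used == 0:
        raise ValueError("no structure present in the target")
    return _const(1.0) - total * (1.0 / used)


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class AdamW:
    """AdamW with decoupled weight decay and per-epoch exponential LR decay."""

    def __init__(self, params: dict, lr=1e-4, weight_decay=1e-5,
                 betas=(0.9, 0.999), eps=1e-8, lr_decay=0.985):
        self.params = params
        self.base_lr = lr
        self.lr = lr
        self.weight_decay = weight_decay
        self.betas = betas
        self.eps = eps
        self.lr_decay = lr_decay
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def set_epoch(self, epoch: int):
        self.lr = self.base_lr * self.lr_decay**epoch

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            p.data -= self.lr * (mhat / (np.sqrt(vhat) + self.eps)
                                 + self.weight_decay * p.data)

    def zero_grad(self):
        for p in self.params.values():
            p.zero_grad()
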