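"""Compact reverse-mode automatic differentiation core on numpy arrays.

Provides exactly the tensor operations the segmentation and detection
networks need: broadcasted arithmetic, elementwise nonlinearities,
reductions, gather, channel concatenation, 2-D convolution (arbitrary
stride/dilation, zero padding), 2x2 max pooling and nearest-neighbour
resampling, plus batch normalisation, SGD/AdamW optimizers and a cosine
learning-rate schedule.  Everything is deterministic given the caller's
`numpy.random.Generator`.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "Module",
    "Conv2d",
    "BatchNorm2d",
    "SGD",
    "AdamW",
    "cosine_lr",
    "xlog",
    "xexp",
    "xarctan",
    "xclip",
    "xmaximum",
    "xminimum",
    "xsigmoid",
    "xmean",
    "xsum",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """An n-d array node in a dynamically built computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    # defer mixed ndarray/Tensor arithmetic to the Tensor operators
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._backward = None

    # ---- graph plumbing -------------------------------------------------
    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    def item(self) -> float:
        return float(self.data)

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo, seen = [], set()

        def visit(node):
            if id(node) in seen or not node.requires_grad:
                return
            seen.add(id(node))
            for p in node._parents:
                visit(p)
            topo.append(node)

        visit(self)
        for node in topo:
            node.grad = np.zeros_like(node.data)
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    # ---- arithmetic -----------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)

        def bwd(g):
            if self.requires_grad:
                self.grad += _unbroadcast(g, self.data.shape)
            if other.requires_grad:
                other.grad += _unbroadcast(g, other.data.shape)

        return self._make(self.data + other.data, (self, other), bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g):
            if self.requires_grad:
                self.grad += -g

        return self._make(-self.data, (self,), bwd)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)

        def bwd(g):
            if self.requires_grad:
                self.grad += _unbroadcast(g * other.data, self.data.shape)
            if other.requires_grad:
                other.grad += _unbroadcast(g * self.data, other.data.shape)

        return self._make(self.data * other.data, (self, other), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)

        def bwd(g):
            if self.requires_grad:
                self.grad += _unbroadcast(g / other.data, self.data.shape)
            if other.requires_grad:
                other.grad += _unbroadcast(
                    -g * self.data / (other.data * other.data), other.data.shape
                )

        return self._make(self.data / other.data, (self, other), bwd)

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    def __pow__(self, p: float):
        def bwd(g):
            if self.requires_grad:
                self.grad += g * p * np.power(self.data, p - 1)

        return self._make(np.power(self.data, p), (self,), bwd)

    # ---- elementwise ----------------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def bwd(g):
            if self.requires_grad:
                self.grad += g * out_data

        return self._make(out_data, (self,), bwd)

    def log(self):
        def bwd(g):
            if self.requires_grad:
                self.grad += g / self.data

        return self._make(np.log(self.data), (self,), bwd)

    def arctan(self):
        def bwd(g):
            if self.requires_grad:
                self.grad += g / (1.0 + self.data * self.data)

        return self._make(np.arctan(self.data), (self,), bwd)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def bwd(g):
            if self.requires_grad:
                self.grad += g * out_data * (1.0 - out_data)

        return self._make(out_data, (self,), bwd)

    def relu(self):
        mask = self.data > 0

        def bwd(g):
            if self.requires_grad:
                self.grad += g * mask

        return self._make(self.data * mask, (self,), bwd)

    def maximum(self, other):
        other = self._wrap(other)
        take_self = self.data >= other.data

        def bwd(g):
            if self.requires_grad:
                self.grad += _unbroadcast(g * take_self, self.data.shape)
            if other.requires_grad:
                other.grad += _unbroadcast(g * ~take_self, other.data.shape)

        return self._make(np.where(take_self, self.data, other.data), (self, other), bwd)

    def minimum(self, other):
        other = self._wrap(other)
        take_self = self.data <= other.data

        def bwd(g):
            if self.requires_grad:
                self.grad += _unbroadcast(g * take_self, self.data.shape)
            if other.requires_grad:
                other.grad += _unbroadcast(g * ~take_self, other.data.shape)

        return self._make(np.where(take_self, self.data, other.data), (self, other), bwd)

    def clip(self, lo: float, hi: float):
        """Clamp with zero gradient outside [lo, hi] (saturating bounds)."""
        inside = (self.data >= lo) & (self.data <= hi)

        def bwd(g):
            if self.requires_grad:
                self.grad += g * inside

        return self._make(np.clip(self.data, lo, hi), (self,), bwd)

    # ---- reductions / shaping -------------------------------------------
    def sum(self, axis=None, keepdims=False):
        def bwd(g):
            if not self.requires_grad:
                return
            if axis is None:
                self.grad += np.broadcast_to(g, self.data.shape)
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self.grad += np.broadcast_to(gg, self.data.shape)

        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), bwd)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    def reshape(self, *shape):
        old = self.data.shape

        def bwd(g):
            if self.requires_grad:
                self.grad += g.reshape(old)

        return self._make(self.data.reshape(*shape), (self,), bwd)

    def transpose(self, *axes):
        inv = np.argsort(axes)

        def bwd(g):
            if self.requires_grad:
                self.grad += g.transpose(*inv)

        return self._make(self.data.transpose(*axes), (self,), bwd)

    def gather(self, idx):
        """Advanced integer indexing; gradients scatter-add back."""

        def bwd(g):
            if self.requires_grad:
                np.add.at(self.grad, idx, g)

        return self._make(self.data[idx], (self,), bwd)

    # ---- spatial ops (NCHW) ---------------------------------------------
    def conv2d(self, weight: "Tensor", bias: "Tensor", stride: int = 1,
               dilation: int = 1, padding: int | None = None):
        """2-D convolution (cross-correlation), zero padded.

        weight: (Cout, Cin, k, k); default padding keeps 'same' size at
        stride 1 for odd k.
        """
        x, w = self, weight
        n, cin, h, wd = x.data.shape
        cout, cin_w, k, _ = w.data.shape
        assert cin == cin_w, "channel mismatch"
        if padding is None:
            padding = dilation * (k - 1) // 2
        span = dilation * (k - 1) + 1
        xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
        hp, wp = xp.shape[2], xp.shape[3]
        ho = (hp - span) // stride + 1
        wo = (wp - span) // stride + 1
        out = np.zeros((n, ho, wo, cout))
        slices = []
        for i in range(k):
            for j in range(k):
                sl = (
                    slice(None), slice(None),
                    slice(i * dilation, i * dilation + (ho - 1) * stride + 1, stride),
                    slice(j * dilation, j * dilation + (wo - 1) * stride + 1, stride),
                )
                slices.append(sl)
                out += np.tensordot(xp[sl], w.data[:, :, i, j], axes=([1], [1]))
        out = np.moveaxis(out, 3, 1)
        if bias is not None:
            out = out + bias.data.reshape(1, cout, 1, 1)

        parents = (x, w) if bias is None else (x, w, bias)

        def bwd(g):
            # g: (N, Cout, Ho, Wo)
            gm = np.moveaxis(g, 1, 3)  # (N, Ho, Wo, Cout)
            if bias is not None and bias.requires_grad:
                bias.grad += g.sum(axis=(0, 2, 3))
            need_x = x.requires_grad
            gxp = np.zeros_like(xp) if need_x else None
            for t, (i, j) in enumerate((i, j) for i in range(k) for j in range(k)):
                sl = slices[t]
                if w.requires_grad:
                    w.grad[:, :, i, j] += np.tensordot(
                        gm, xp[sl], axes=([0, 1, 2], [0, 2, 3])
                    )
                if need_x:
                    gxp[sl] += np.moveaxis(
                        np.tensordot(gm, w.data[:, :, i, j], axes=([3], [0])), 3, 1
                    )
            if need_x:
                if padding:
                    x.grad += gxp[:, :, padding:hp - padding, padding:wp - padding]
                else:
                    x.grad += gxp

        return self._make(out, parents, bwd)

    def maxpool2(self):
        """2x2 max pooling, stride 2, ceil mode (odd edges padded)."""
        n, c, h, w = self.data.shape
        ph, pw = (-h) % 2, (-w) % 2
        xp = np.pad(self.data, ((0, 0), (0, 0), (0, ph), (0, pw)),
                    constant_values=-np.inf)
        ho, wo = xp.shape[2] // 2, xp.shape[3] // 2
        xr = xp.reshape(n, c, ho, 2, wo, 2).transpose(0, 1, 2, 4, 3, 5)
        xr = xr.reshape(n, c, ho, wo, 4)
        arg = xr.argmax(axis=-1)
        out = np.take_along_axis(xr, arg[..., None], axis=-1)[..., 0]

        def bwd(g):
            if not self.requires_grad:
                return
            gr = np.zeros((n, c, ho, wo, 4))
            np.put_along_axis(gr, arg[..., None], g[..., None], axis=-1)
            gr = gr.reshape(n, c, ho, wo, 2, 2).transpose(0, 1, 2, 4, 3, 5)
            gr = gr.reshape(n, c, ho * 2, wo * 2)
            self.grad += gr[:, :, :h, :w]

        return self._make(out, (self,), bwd)

    def upsample_to(self, th: int, tw: int):
        """Nearest-neighbour resample to (th, tw)."""
        n, c, h, w = self.data.shape
        idx_h = np.minimum((np.arange(th) * h) // th, h - 1)
        idx_w = np.minimum((np.arange(tw) * w) // tw, w - 1)
        out = self.data[:, :, idx_h][:, :, :, idx_w]

        def bwd(g):
            if not self.requires_grad:
                return
            g2 = np.zeros((n, c, h, tw))
            np.add.at(g2, (slice(None), slice(None), idx_h), g)
            np.add.at(self.grad, (slice(None), slice(None), slice(None), idx_w), g2)

        return self._make(out, (self,), bwd)


def concat(tensors: list, axis: int = 1) -> Tensor:
    sizes = [t.data.shape[axis] for t in tensors]
    offs = np.cumsum([0] + sizes)

    def bwd(g):
        for t, a, b in zip(tensors, offs[:-1], offs[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t.grad += g[tuple(sl)]

    return Tensor._make(
        np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), bwd
    )


# ---- Tensor/ndarray dispatch helpers (losses are written once) ----------

def _is_t(x):
    return isinstance(x, Tensor)


def xlog(x):
    return x.log() if _is_t(x) else np.log(x)


def xexp(x):
    return x.exp() if _is_t(x) else np.exp(x)


def xarctan(x):
    return x.arctan() if _is_t(x) else np.arctan(x)


def xclip(x, lo, hi):
    return x.clip(lo, hi) if _is_t(x) else np.clip(x, lo, hi)


def xmaximum(a, b):
    if _is_t(a):
        return a.maximum(b)
    if _is_t(b):
        return b.maximum(a)
    return np.maximum(a, b)


def xminimum(a, b):
    if _is_t(a):
        return a.minimum(b)
    if _is_t(b):
        return b.minimum(a)
    return np.minimum(a, b)


def xsigmoid(x):
    return x.sigmoid() if _is_t(x) else 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def xmean(x):
    return x.mean() if _is_t(x) else float(np.mean(x))


def xsum(x):
    return x.sum() if _is_t(x) else float(np.sum(x))


# ---- modules ------------------------------------------------------------

class Module:
    """Minimal parameter container with train/eval state."""

    def parameters(self) -> list:
        out = []
        for v in vars(self).values():
            if isinstance(v, Tensor) and v.requires_grad:
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        out.append(item)
        return out

    def modules(self) -> list:
        out = [self]
        for v in vars(self).values():
            if isinstance(v, Module):
                out.extend(v.modules())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.modules())
        return out

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def set_training(self, flag: bool):
        for m in self.modules():
            if isinstance(m, BatchNorm2d):
                m.training = flag

    def state_arrays(self) -> list[np.ndarray]:
        """All arrays needed to restore the module (params + BN stats)."""
        arrs = [p.data for p in self.parameters()]
        for m in self.modules():
            if isinstance(m, BatchNorm2d):
                arrs.extend([m.running_mean, m.running_var])
        return arrs

    def load_state_arrays(self, arrs: list[np.ndarray]):
        arrs = list(arrs)
        for p in self.parameters():
            p.data = np.array(arrs.pop(0), dtype=np.float64)
        for m in self.modules():
            if isinstance(m, BatchNorm2d):
                m.running_mean = np.array(arrs.pop(0), dtype=np.float64)
                m.running_var = np.array(arrs.pop(0), dtype=np.float64)


class Conv2d(Module):
    def __init__(self, cin: int, cout: int, k: int = 3, stride: int = 1,
                 dilation: int = 1, rng: np.random.Generator | None = None,
                 bias: bool = True):
        rng = rng or np.random.default_rng(0)
        fan_in = cin * k * k
        scale = math.sqrt(2.0 / fan_in)
        self.weight = Tensor(rng.normal(0.0, scale, (cout, cin, k, k)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(cout), requires_grad=True) if bias else None
        self.stride = stride
        self.dilation = dilation

    def __call__(self, x: Tensor) -> Tensor:
        return x.conv2d(self.weight, self.bias, stride=self.stride,
                        dilation=self.dilation)


class BatchNorm2d(Module):
    def __init__(self, c: int, eps: float = 1e-5, momentum: float = 0.1):
        self.gamma = Tensor(np.ones(c), requires_grad=True)
        self.beta = Tensor(np.zeros(c), requires_grad=True)
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)
        self.eps = eps
        self.momentum = momentum
        self.training = True

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            axes = (0, 2, 3)
            mu = x.data.mean(axis=axes)
            var = x.data.var(axis=axes)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mu
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
            inv = 1.0 / np.sqrt(var + self.eps)
            m = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
            xhat = (x.data - mu.reshape(1, -1, 1, 1)) * inv.reshape(1, -1, 1, 1)
            gamma, beta = self.gamma, self.beta

            def bwd(g):
                dxhat = g * gamma.data.reshape(1, -1, 1, 1)
                if gamma.requires_grad:
                    gamma.grad += (g * xhat).sum(axis=axes)
                if beta.requires_grad:
                    beta.grad += g.sum(axis=axes)
                if x.requires_grad:
                    s1 = dxhat.sum(axis=axes, keepdims=True)
                    s2 = (dxhat * xhat).sum(axis=axes, keepdims=True)
                    x.grad += (inv.reshape(1, -1, 1, 1) / m) * (
                        m * dxhat - s1 - xhat * s2
                    )

            out_data = xhat * gamma.data.reshape(1, -1, 1, 1) + beta.data.reshape(1, -1, 1, 1)
            return Tensor._make(out_data, (x, gamma, beta), bwd)
        inv = 1.0 / np.sqrt(self.running_var + self.eps)
        scale = Tensor((self.gamma.data * inv).reshape(1, -1, 1, 1))
        scale.data = scale.data  # constant in eval mode
        shift = (self.beta.data - self.gamma.data * self.running_mean * inv).reshape(1, -1, 1, 1)
        gamma, beta = self.gamma, self.beta
        rm, iv = self.running_mean, inv

        def bwd_eval(g):
            if x.requires_grad:
                x.grad += g * (gamma.data * iv).reshape(1, -1, 1, 1)
            if gamma.requires_grad:
                xh = (x.data - rm.reshape(1, -1, 1, 1)) * iv.reshape(1, -1, 1, 1)
                gamma.grad += (g * xh).sum(axis=(0, 2, 3))
            if beta.requires_grad:
                beta.grad += g.sum(axis=(0, 2, 3))

        out_data = x.data * (gamma.data * iv).reshape(1, -1, 1, 1) + shift
        return Tensor._make(out_data, (x, gamma, beta), bwd_eval)


# ---- optimizers ----------------------------------------------------------

class SGD:
    """SGD with Nesterov-free momentum and decoupled weight decay."""

    def __init__(self, params: list[Tensor], lr: float, momentum: float = 0.0,
                 weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.velocity = [np.zeros_like(p.data) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.grad = np.zeros_like(p.data)

    def step(self):
        for p, v in zip(self.params, self.velocity):
            g = p.grad + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= self.lr * v


class AdamW:
    def __init__(self, params: list[Tensor], lr: float = 1e-4,
                 betas: tuple = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = np.zeros_like(p.data)

    def step(self):
        self.t += 1
        bc1 = 1 - self.b1 ** self.t
        bc2 = 1 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.data -= self.lr * self.weight_decay * p.data
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


def cosine_lr(lr0: float, epoch: int, t_max: int, eta_min: float = 0.0) -> float:
    """Closed-form cosine annealing; periodic beyond ``t_max``."""
    return eta_min + 0.5 * (lr0 - eta_min) * (1.0 + math.cos(math.pi * epoch / t_max))
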