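"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the training objectives need: elementwise
arithmetic, matrix products, reductions, sigmoid/log/relu/sqrt, clipping,
3D cross-correlation (implemented with scipy), strided subsampling, and a
``detach`` stop-gradient. Gradients are accumulated by a reverse topological
sweep over the recorded tape.

The engine is deliberately tiny: the package's backbones are small enough
that clarity and determinism matter more than kernel-level speed.
"""

from __future__ import annotations

import numpy as np
from scipy import signal


class Tensor:
    """A numpy array with an optional gradient tape entry.

    Parameters
    ----------
    data : array_like
        Wrapped value, stored as float64.
    requires_grad : bool
        Whether gradients should be accumulated into ``.grad``.
    """

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")
    __array_priority__ = 100  # numpy defers binary ops to Tensor

    def __init__(self, data, requires_grad=False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents = ()

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @property
    def shape(self):
        return self.data.shape

    def item(self) -> float:
        return float(self.data)

    def __float__(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- autodiff machinery ---------------------------------------------------
    def detach(self) -> "Tensor":
        """Stop-gradient: same value, no tape connection."""
        return Tensor(self.data.copy(), requires_grad=False)

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        grads = {id(self): np.asarray(grad, dtype=np.float64)}
        for t in reversed(topo):
            g = grads.pop(id(t), None)
            if g is None:
                continue
            if t.requires_grad:
                t.grad = g if t.grad is None else t.grad + g
            if t._backward is not None:
                for parent, pg in zip(t._parents, t._backward(g)):
                    if pg is None:
                        continue
                    key = id(parent)
                    grads[key] = pg if key not in grads else grads[key] + pg

    def zero_grad(self):
        self.grad = None

    # -- operator sugar -------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, mul(Tensor._lift(other), -1.0))

    def __rsub__(self, other):
        return add(Tensor._lift(other), mul(self, -1.0))

    def __truediv__(self, other):
        return mul(self, power(Tensor._lift(other), -1.0))

    def __pow__(self, p):
        return power(self, p)

    def __matmul__(self, other):
        return matmul(self, other)

    def sum(self):
        return sum_(self)

    def mean(self):
        return mean(self)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) != 1 else shape[0])


def _node(data, parents, backward):
    out = Tensor(data)
    if any(p.requires_grad or p._parents for p in parents):
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _unbroadcast(g, shape):
    """Reduce gradient g back to ``shape`` after numpy broadcasting."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g.reshape(shape)


def add(a, b):
    a, b = Tensor._lift(a), Tensor._lift(b)
    return _node(
        a.data + b.data,
        (a, b),
        lambda g: (_unbroadcast(g, a.shape), _unbroadcast(g, b.shape)),
    )


def mul(a, b):
    a, b = Tensor._lift(a), Tensor._lift(b)
    return _node(
        a.data * b.data,
        (a, b),
        lambda g: (_unbroadcast(g * b.data, a.shape), _unbroadcast(g * a.data, b.shape)),
    )


def matmul(a, b):
    """Matrix product for (m,n)@(n,k) or (n,)@(n,k)."""
    a, b = Tensor._lift(a), Tensor._lift(b)
    if b.data.ndim != 2:
        raise ValueError("matmul rhs must be 2-D")

    def back(g):
        ga = g @ b.data.T
        gb = np.outer(a.data, g) if a.data.ndim == 1 else a.data.T @ g
        return (ga, gb)

    return _node(a.data @ b.data, (a, b), back)


def power(a, p):
    a = Tensor._lift(a)
    p = float(p)
    return _node(
        a.data ** p,
        (a,),
        lambda g: (g * p * a.data ** (p - 1.0),),
    )


def sqrt(a):
    return power(a, 0.5)


def sum_(a):
    a = Tensor._lift(a)
    return _node(a.data.sum(), (a,), lambda g: (np.broadcast_to(g, a.shape).copy(),))


def mean(a):
    a = Tensor._lift(a)
    n = a.data.size
    return _node(
        a.data.mean(), (a,), lambda g: (np.broadcast_to(g / n, a.shape).copy(),)
    )


def log(a):
    a = Tensor._lift(a)
    return _node(np.log(a.data), (a,), lambda g: (g / a.data,))


def sigmoid(a):
    a = Tensor._lift(a)
    s = 1.0 / (1.0 + np.exp(-a.data))
    return _node(s, (a,), lambda g: (g * s * (1.0 - s),))


def relu(a):
    a = Tensor._lift(a)
    m = a.data > 0
    return _node(a.data * m, (a,), lambda g: (g * m,))


def clip(a, lo, hi):
    """Clip values; gradient passes through the un-clipped interior only."""
    a = Tensor._lift(a)
    m = (a.data >= lo) & (a.data <= hi)
    return _node(np.clip(a.data, lo, hi), (a,), lambda g: (g * m,))


def reshape(a, shape):
    a = Tensor._lift(a)
    old = a.shape
    return _node(a.data.reshape(shape), (a,), lambda g: (g.reshape(old),))


def concat(tensors):
    """Stack 1-D tensors into one 1-D tensor."""
    ts = [Tensor._lift(t) for t in tensors]
    sizes = [t.data.size for t in ts]
    offs = np.cumsum([0] + sizes)

    def back(g):
        return tuple(
            g[offs[i]: offs[i + 1]].reshape(ts[i].shape) for i in range(len(ts))
        )

    return _node(np.concatenate([t.data.ravel() for t in ts]), ts, back)


def stack(tensors):
    """Stack same-shape tensors along a new leading axis."""
    ts = [Tensor._lift(t) for t in tensors]
    return _node(
        np.stack([t.data for t in ts]),
        ts,
        lambda g: tuple(g[i] for i in range(len(ts))),
    )


def subsample(a, stride):
    """Strided slicing a[::sz, ::sy, ::sx] over the trailing 3 axes."""
    a = Tensor._lift(a)
    sl = (Ellipsis,) + tuple(slice(None, None, s) for s in stride)

    def back(g):
        full = np.zeros_like(a.data)
        full[sl] = g
        return (full,)

    return _node(a.data[sl].copy(), (a,), back)


def correlate3d(a, kernel, bias=None):
    """'Same'-padded 3D cross-correlation of a (D,H,W) tensor with a kernel.

    Border handling is zero padding; gradient w.r.t. the kernel is the
    valid correlation of the padded input with the output gradient.
    """
    a, kernel = Tensor._lift(a), Tensor._lift(kernel)
    k = kernel.data
    pads = [((s - 1) // 2, s - 1 - (s - 1) // 2) for s in k.shape]

    def corr(x, w):
        xp = np.pad(x, pads)
        return signal.correlate(xp, w, mode="valid")

    out = corr(a.data, k)

    def back(g):
        # input grad: full convolution (correlate with flipped kernel)
        gi = signal.convolve(g, k, mode="full")
        sl = tuple(slice(p0, gi.shape[i] - p1) for i, (p0, p1) in enumerate(pads))
        gi = gi[sl]
        gk = signal.correlate(np.pad(a.data, pads), g, mode="valid")
        return (gi, gk)

    res = _node(out, (a, kernel), back)
    if bias is not None:
        res = add(res, bias)
    return res


def neg_cosine(a, b):
    """Negative cosine similarity −⟨a,b⟩ / (‖a‖₂ ‖b‖₂) of two nonzero vectors."""
    a, b = Tensor._lift(a), Tensor._lift(b)
    if float(np.linalg.norm(a.data)) == 0.0 or float(np.linalg.norm(b.data)) == 0.0:
        raise ValueError("neg_cosine requires nonzero vectors")
    num = sum_(mul(a, b))
    den = sqrt(mul(sum_(mul(a, a)), sum_(mul(b, b))))
    return mul(mul(num, power(den, -1.0)), -1.0)


class Adam:
    """Adam optimizer over a list of parameter Tensors (standard moments)."""

    def __init__(self, params, lr=1e-4, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
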